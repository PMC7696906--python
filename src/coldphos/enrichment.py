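"""Gene-ontology over-representation analysis.

Per-term significance uses the one-sided Fisher exact test (hypergeometric
enrichment) of study hits against an annotated background; multiple testing is
controlled with the Benjamini-Yekutieli step-up procedure, which is valid
under arbitrary dependence between terms (nested GO terms are strongly
dependent). Terms with fewer than ``min_mapped`` study hits are not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable

logger = logging.getLogger(__name__)

# Membrane/periphery compartments of interest (Group A) vs soluble/organellar
# compartments excluded from the membrane-fraction analysis (Group B).
GROUP_A_KEYWORDS = (
    "plasma membrane", "endoplasmic reticulum", "golgi", "vacuole",
    "extracellular", "cell wall", "apoplast", "cytoskeleton", "plasmodesma",
)
GROUP_B_KEYWORDS = ("cytosol", "mitochondria", "plastid", "nucleus", "complex")


def fisher_exact(table, alternative: str = "greater") -> float:
    """Fisher exact p for a 2x2 contingency table of non-negative ints."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("contingency cells must be non-negative")
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def adjust_by(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (harmonic-number factor)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_by")[1]


@dataclass
class ORAResult:
    """Per-term enrichment rows plus the inputs that framed them."""

    table: pd.DataFrame
    study_size: int
    background_size: int
    aspect: str


def run_ora(study_genes, background_genes, annotations: AnnotationTable,
            aspect: str, min_mapped: int = 5, alpha: float = 0.05) -> ORAResult:
    """One-sided Fisher ORA of a study set against a background, BY-adjusted.

    Only terms with at least ``min_mapped`` study hits are tested;
    ``significant`` marks adjusted p <= alpha.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    ann = annotations.for_aspect(aspect)
    if ann.empty:
        logger.warning("no %s annotations available", aspect)
        return ORAResult(pd.DataFrame(columns=[
            "go_id", "aspect", "study_hits", "study_size", "background_hits",
            "background_size", "odds_ratio", "p_value", "p_adj", "significant",
        ]), len(study), len(background), aspect)

    n, N = len(study), len(background)
    rows = []
    for go_id, genes in ann.groupby("go_id")["gene_id"]:
        term_genes = set(genes) & background
        k = len(term_genes & study)
        if k < min_mapped:
            continue
        K = len(term_genes)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        p = fisher_exact(table, alternative="greater")
        odds = np.inf
        if (n - k) * (K - k) > 0:
            odds = (k * (N - n - (K - k))) / ((n - k) * (K - k))
        rows.append({"go_id": go_id, "aspect": aspect, "study_hits": k,
                     "study_size": n, "background_hits": K,
                     "background_size": N, "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(rows)
    if df.empty:
        logger.warning("no %s terms reach min_mapped=%d study hits",
                       aspect, min_mapped)
        df = pd.DataFrame(columns=[
            "go_id", "aspect", "study_hits", "study_size", "background_hits",
            "background_size", "odds_ratio", "p_value"])
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return ORAResult(df, n, N, aspect)
    df["p_adj"] = adjust_by(df["p_value"].to_numpy())
    df["significant"] = df["p_adj"] <= alpha
    df = df.sort_values("p_value").reset_index(drop=True)
    return ORAResult(df, n, N, aspect)


def split_localization_groups(proteins, cc_annotations: AnnotationTable,
                              unannotated_to: str = "B"
                              ) -> tuple[set[str], set[str]]:
    """Split proteins into the membrane/periphery group of interest (A) and
    the soluble/organellar group (B) by cellular-component annotation.

    Any qualifying membrane-compartment annotation sends a protein to Group A
    (any-membership rule); proteins annotated only to Group-B compartments go
    to B; unannotated proteins go to ``unannotated_to`` (default B).
    """
    if unannotated_to not in ("A", "B"):
        raise ValueError("unannotated_to must be 'A' or 'B'")
    ann = cc_annotations.for_aspect("CC")
    terms_by_gene: dict[str, set[str]] = {}
    for gene, go in zip(ann["gene_id"], ann["go_id"]):
        terms_by_gene.setdefault(gene, set()).add(go.lower())

    group_a: set[str] = set()
    group_b: set[str] = set()
    for prot in proteins:
        terms = terms_by_gene.get(prot)
        if not terms:
            (group_a if unannotated_to == "A" else group_b).add(prot)
            continue
        in_a = any(kw in t for t in terms for kw in GROUP_A_KEYWORDS)
        (group_a if in_a else group_b).add(prot)
    logger.info("localization split: %d Group A, %d Group B",
                len(group_a), len(group_b))
    return group_a, group_b
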