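"""Synthetic cold-exposure phosphoproteomics study with known ground truth.

Generates the four external artifacts the pipeline consumes — a quantified
phosphopeptide table over 0/5/15/30/60 min x 3 replicates, a proteome, a GO
annotation table and a kinase-substrate interaction table — together with a
:class:`GroundTruth` object recording every planted signal, so that filtering,
normalization, clustering, differential calling, enrichment, motif extraction
and subnetwork mapping can all be scored against truth.

The temporal signal follows eight archetype trajectories: transient
phosphorylation peaks at 5, 15, 30 or 60 min (A-D), sustained phosphorylation
(E), continuous dephosphorylation (F), fluctuating dephosphorylation with no
positive excursion (G), and no response (H).

Sequence design: every phosphosite sits at the center of a 13-residue window
whose non-central positions are drawn from the 17 non-S/T/Y amino acids, so a
protein contributes exactly one S/T/Y-centered window per planted site and the
prevalence of any planted motif is controlled exactly (windows either match a
planted pattern or are explicitly resampled not to match it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationTable,
    InteractionTable,
    PhosphopeptideRecord,
    ProteomeDb,
    QuantTable,
)

logger = logging.getLogger(__name__)

ARCHETYPES = ("A", "B", "C", "D", "E", "F", "G", "H")
COLD_TIMES = (5, 15, 30, 60)
TIMES = (0,) + COLD_TIMES
N_REPLICATES = 3

# relative mean log2FC shapes at (5, 15, 30, 60) min, scaled by effect_size
_SHAPES = {
    "A": (1.0, 0.25, 0.10, 0.0),
    "B": (0.10, 1.0, 0.25, 0.05),
    "C": (0.0, 0.10, 1.0, 0.25),
    "D": (0.05, 0.10, 0.25, 1.0),
    "E": (1.0, 0.60, 0.70, 0.90),     # sustained: all >= e/2
    "F": (-0.50, -0.70, -0.85, -1.0),  # continuous dephosphorylation
    "G": (-1.0, -0.25, -1.0, -0.50),   # fluctuating dephosphorylation
    "H": (0.0, 0.0, 0.0, 0.0),
}

_NON_STY = np.array(list("ACDEFGHIKLMNPQRVW"))  # 17 letters, no S/T/Y
_STY_PROBS = {"S": 0.85, "T": 0.12, "Y": 0.03}

GROUP_A_COMPARTMENTS = (
    "plasma membrane", "endoplasmic reticulum", "Golgi", "vacuole",
    "extracellular", "cell wall", "apoplast", "cytoskeleton", "plasmodesmata",
)
GROUP_B_COMPARTMENTS = ("cytosol", "mitochondria", "plastid", "nucleus")

KINASE_FAMILIES = (
    "MAPK", "SnRK", "CDPK-CaMK", "LRR-RLK", "AGC-STK", "SLK-GSK", "CK-CKL",
    "other",
)


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    ``n_per_archetype`` maps archetype labels A-H to row counts (an int applies
    to all eight). ``effect_size`` is the mean |log2FC| at a profile's peak;
    ``noise_sd`` the replicate-level Gaussian noise on the log2 scale.
    ``planted_motifs`` is a list of ``(pattern, fg_prevalence, bg_prevalence)``
    where pattern is a 13-character string with '.' wildcards and the central
    residue at index 6 (e.g. ``"...R..S......"`` for R at -3 of a pS site).
    """

    n_per_archetype: dict[str, int] | int = 100
    effect_size: float = 1.5
    noise_sd: float = 0.25
    missing_rate: float = 0.05
    planted_motifs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("...R..S......", 0.40, 0.05),
                                 ("......S.P....", 0.30, 0.05)])
    n_background_proteins: int = 300
    batch_bias: float | None = None
    seed: int | None = None
    doubly_phospho_fraction: float = 0.10
    low_loc_prob_fraction: float = 0.10
    signal_go_fg_rate: float = 0.50
    signal_go_bg_rate: float = 0.05
    n_kinases: int = 30

    def counts(self) -> dict[str, int]:
        if isinstance(self.n_per_archetype, int):
            return {a: self.n_per_archetype for a in ARCHETYPES}
        out = {a: int(self.n_per_archetype.get(a, 0)) for a in ARCHETYPES}
        unknown = set(self.n_per_archetype) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype labels: {sorted(unknown)}")
        return out

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory for reproducibility")
        if any(n < 0 for n in self.counts().values()):
            raise ValueError("n_per_archetype entries must be >= 0")
        for pattern, fg, bg in self.planted_motifs:
            if len(pattern) != 13:
                raise ValueError(f"motif pattern {pattern!r} must be 13 characters")
            if pattern[6] not in "STY":
                raise ValueError(f"motif pattern {pattern!r} center must be S/T/Y")
            if not (0 <= fg <= 1 and 0 <= bg <= 1):
                raise ValueError("motif prevalences must lie in [0,1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")


@dataclass
class GroundTruth:
    """Everything that was planted: per-peptide labels and effects, per-protein
    GO signal, and the rank-1 bias trend if one was added."""

    peptides: pd.DataFrame      # peptide_id, protein_id, archetype, peak_time,
                                # fc_5..fc_60, motif_<i> flags, low_loc_prob
    proteins: pd.DataFrame      # protein_id, is_study, is_early, has_signal_go
    signal_go_id: str
    bias_trend: np.ndarray | None   # unit-norm, one entry per sample column
    sample_columns: list[str]


def archetype_profile(label: str, effect_size: float) -> np.ndarray:
    """Mean log2FC at (5, 15, 30, 60) min for one temporal archetype."""
    if label not in _SHAPES:
        raise ValueError(f"unknown archetype label {label!r}")
    return effect_size * np.asarray(_SHAPES[label], dtype=float)


def _pattern_constraints(pattern: str) -> list[tuple[int, str]]:
    """Non-central fixed positions of a planted pattern as (index, residue)."""
    return [(i, c) for i, c in enumerate(pattern) if c != "." and i != 6]


def _random_window(rng: np.random.Generator, center: str) -> list[str]:
    w = list(rng.choice(_NON_STY, size=13))
    w[6] = center
    return w


def _apply_pattern(window: list[str], pattern: str, match: bool,
                   rng: np.random.Generator) -> None:
    """Force ``window`` to match (or explicitly not match) ``pattern``."""
    cons = _pattern_constraints(pattern)
    if not cons:
        return
    if match:
        for i, res in cons:
            window[i] = res
    else:
        if all(window[i] == res for i, res in cons):
            i, res = cons[rng.integers(len(cons))]
            choices = [a for a in _NON_STY if a != res]
            window[i] = choices[rng.integers(len(choices))]


def _draw_center(rng: np.random.Generator) -> str:
    return rng.choice(list(_STY_PROBS), p=list(_STY_PROBS.values()))


def simulate_dataset(config: SimConfig) -> tuple[
        QuantTable, ProteomeDb, AnnotationTable, InteractionTable, GroundTruth]:
    """Generate the full synthetic study. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    sample_cols = [f"{t}min_rep{r}" for t in TIMES for r in range(1, N_REPLICATES + 1)]

    # --- peptides, proteins, windows -------------------------------------
    records: list[PhosphopeptideRecord] = []
    proteins: dict[str, str] = {}
    truth_rows = []
    motif_flags_all: list[list[bool]] = []
    pep_idx = 0
    for label in ARCHETYPES:
        profile = archetype_profile(label, config.effect_size)
        responsive_up = label in ("A", "B", "C", "D", "E")
        for _ in range(counts[label]):
            pep_idx += 1
            pid = f"pep{pep_idx:05d}"
            prot = f"STUDY{pep_idx:05d}"
            doubly = rng.random() < config.doubly_phospho_fraction
            # peptide: one 13-mer window per site; doubly phosphorylated
            # peptides are 21-mers with site centers 8 apart (no window overlap
            # at the S/T/Y positions)
            flags = []
            if doubly:
                c1, c2 = _draw_center(rng), _draw_center(rng)
                w1 = _random_window(rng, c1)
                tail = list(rng.choice(_NON_STY, size=8))
                pep = w1 + tail
                pep[14] = c2
                for pat, fg_prev, bg_prev in config.planted_motifs:
                    match = responsive_up and c1 == pat[6] and rng.random() < fg_prev
                    _apply_pattern(pep, pat, match, rng)
                    flags.append(bool(match))
                sites_in_pep = [(7, c1), (15, pep[14])]
            else:
                c1 = _draw_center(rng)
                pep = _random_window(rng, c1)
                for pat, fg_prev, bg_prev in config.planted_motifs:
                    match = responsive_up and c1 == pat[6] and rng.random() < fg_prev
                    _apply_pattern(pep, pat, match, rng)
                    flags.append(bool(match))
                sites_in_pep = [(7, pep[6])]
            motif_flags_all.append(flags)
            pep_seq = "".join(pep)
            flank_n = "".join(rng.choice(_NON_STY, size=10))
            flank_c = "".join(rng.choice(_NON_STY, size=10))
            proteins[prot] = flank_n + pep_seq + flank_c
            offset = len(flank_n)
            sites = [(offset + p, res) for p, res in sites_in_pep]
            low_loc = rng.random() < config.low_loc_prob_fraction
            if low_loc:
                probs = [float(rng.uniform(0.40, 0.75)) for _ in sites]
            else:
                probs = [float(rng.uniform(0.90, 1.0)) for _ in sites]
            records.append(PhosphopeptideRecord(
                peptide_id=pid, sequence=pep_seq, protein_id=prot,
                sites=sites, loc_probability=probs))
            truth_rows.append({
                "peptide_id": pid, "protein_id": prot, "archetype": label,
                "peak_time": COLD_TIMES[int(np.argmax(np.abs(profile)))]
                if label != "H" else 0,
                "low_loc_prob": low_loc,
                **{f"fc_{t}": profile[i] for i, t in enumerate(COLD_TIMES)},
            })

    # background proteins: non-overlapping STY-centered window blocks joined
    # by non-STY spacers, with controlled planted-motif prevalence
    for b in range(config.n_background_proteins):
        blocks = []
        for _ in range(4):
            center = _draw_center(rng)
            w = _random_window(rng, center)
            for pat, fg_prev, bg_prev in config.planted_motifs:
                if center == pat[6]:
                    _apply_pattern(w, pat, rng.random() < bg_prev, rng)
            blocks.append("".join(w))
        spacer = "".join(rng.choice(_NON_STY, size=2))
        proteins[f"BG{b:05d}"] = spacer.join(blocks)

    # --- intensities ------------------------------------------------------
    n_pep = len(records)
    base_mu = rng.normal(20.0, 2.0, size=n_pep)          # log2 baseline level
    log2 = np.empty((n_pep, len(sample_cols)))
    truth_df = pd.DataFrame(truth_rows)
    fc_matrix = truth_df[[f"fc_{t}" for t in COLD_TIMES]].to_numpy()
    for j, col in enumerate(sample_cols):
        t = int(col.split("min")[0])
        shift = np.zeros(n_pep) if t == 0 else fc_matrix[:, COLD_TIMES.index(t)]
        log2[:, j] = base_mu + shift + rng.normal(0.0, config.noise_sd, size=n_pep)

    bias_trend = None
    if config.batch_bias:
        # replicate-batch drift: constant within each replicate across times,
        # hence orthogonal to the time-point treatment structure (a bias that
        # is collinear with treatment would be unidentifiable by any
        # fold-change-preserving normalization)
        rep_idx = np.array([int(c.split("_rep")[1]) for c in sample_cols], float)
        trend = rep_idx - rep_idx.mean()
        trend /= np.linalg.norm(trend)
        loadings = rng.normal(0.0, 1.0, size=n_pep)
        log2 += config.batch_bias * np.outer(loadings, trend)
        bias_trend = trend

    intensities = np.power(2.0, log2)
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities[mask] = np.nan

    quant = QuantTable(
        records=records, times=list(TIMES),
        replicates=list(range(1, N_REPLICATES + 1)),
        intensities=pd.DataFrame(
            intensities, columns=sample_cols,
            index=pd.Index([r.peptide_id for r in records], name="peptide_id")))

    for i, (pat, _, _) in enumerate(config.planted_motifs):
        truth_df[f"motif_{i}"] = [f[i] for f in motif_flags_all]

    # --- annotations ------------------------------------------------------
    signal_go = "GO:9000001"
    early_prots = set(truth_df.loc[truth_df.archetype.isin(["A", "B"]),
                                   "protein_id"])
    ann_rows = []
    prot_rows = []
    generic_bp = [f"GO:80000{i:02d}" for i in range(20)]
    for pid in proteins:
        is_study = pid.startswith("STUDY")
        is_early = pid in early_prots
        if is_early:
            has_signal = rng.random() < config.signal_go_fg_rate
        else:
            has_signal = rng.random() < config.signal_go_bg_rate
        if has_signal:
            ann_rows.append((pid, signal_go, "BP", "IDA"))
        for term in generic_bp:
            if rng.random() < 0.10:
                code = "IEA" if rng.random() < 0.10 else "EXP"
                ann_rows.append((pid, term, "BP", code))
        # cellular component: study proteins mostly membrane-associated
        if is_study:
            comp_pool = GROUP_A_COMPARTMENTS if rng.random() < 0.8 else GROUP_B_COMPARTMENTS
        else:
            comp_pool = GROUP_A_COMPARTMENTS if rng.random() < 0.3 else GROUP_B_COMPARTMENTS
        comp = comp_pool[rng.integers(len(comp_pool))]
        ann_rows.append((pid, f"GO:CC:{comp}", "CC", "IDA"))
        prot_rows.append({"protein_id": pid, "is_study": is_study,
                          "is_early": is_early, "has_signal_go": has_signal,
                          "compartment": comp})
    annotations = AnnotationTable(table=pd.DataFrame(
        ann_rows, columns=["gene_id", "go_id", "aspect", "evidence_code"]))

    # --- kinase-substrate interactions ------------------------------------
    study_prots = [p for p in proteins if p.startswith("STUDY")]
    inter_rows = []
    for k in range(config.n_kinases):
        kid = f"KIN{k:03d}"
        fam = KINASE_FAMILIES[rng.integers(len(KINASE_FAMILIES))]
        n_sub = int(rng.integers(3, 12))
        subs = rng.choice(study_prots, size=min(n_sub, len(study_prots)),
                          replace=False)
        for s in subs:
            inter_rows.append((kid, s, fam, "synthetic"))
    interactions = InteractionTable(table=pd.DataFrame(
        inter_rows, columns=["kinase_id", "substrate_id", "kinase_family",
                             "source"]).assign(site=pd.NA))

    truth = GroundTruth(
        peptides=truth_df, proteins=pd.DataFrame(prot_rows),
        signal_go_id=signal_go, bias_trend=bias_trend,
        sample_columns=sample_cols)
    logger.info("simulated %d peptides, %d proteins, %d annotations, %d interactions",
                n_pep, len(proteins), len(annotations), len(interactions))
    return quant, ProteomeDb(sequences=proteins), annotations, interactions, truth
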