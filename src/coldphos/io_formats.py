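"""Readers and writers for the external tables and sequences the pipeline touches.

Conventions
-----------
* Phosphosite positions are **1-based** protein coordinates everywhere — in the
  external TSV files and in memory — matching the field's ``pS279`` notation.
* Missing intensities are *absent* (``NaN`` in memory, empty or ``NA`` on disk);
  a zero intensity is a measured value, not a missing one.
* Intensity columns are named ``<time>min_rep<k>`` (e.g. ``5min_rep2``) and are
  normalized to (time ascending, replicate ascending) order on load.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_RESIDUES = {"S", "T", "Y"}
_VALID_ASPECTS = {"BP", "MF", "CC"}
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

_INTENSITY_COL_RE = re.compile(r"^(\d+)min_rep(\d+)$")
_SITE_TOKEN_RE = re.compile(r"^([STY])(\d+)$")


@dataclass
class PhosphopeptideRecord:
    """One quantified phosphopeptide form.

    ``sites`` holds ``(position_in_protein, residue)`` pairs with 1-based
    positions; ``loc_probability`` aligns with ``sites``.
    """

    peptide_id: str
    sequence: str
    protein_id: str
    sites: list[tuple[int, str]]
    loc_probability: list[float]

    @property
    def multiplicity(self) -> int:
        return len(self.sites)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sites) != len(self.loc_probability):
            raise ValueError(
                f"peptide {self.peptide_id}: {len(self.sites)} sites but "
                f"{len(self.loc_probability)} localization probabilities"
            )
        for pos, res in self.sites:
            if res not in _VALID_RESIDUES:
                raise ValueError(
                    f"peptide {self.peptide_id}: site residue {res!r} not in S/T/Y"
                )
            if pos < 1:
                raise ValueError(
                    f"peptide {self.peptide_id}: site position {pos} not 1-based positive"
                )
        for p in self.loc_probability:
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"peptide {self.peptide_id}: localization probability {p} outside [0,1]"
                )


@dataclass
class QuantTable:
    """A quantified phosphopeptide intensity table.

    ``intensities`` is indexed by ``peptide_id`` with one column per
    ``(time, replicate)`` sample, named ``<time>min_rep<k>``; missing cells
    are NaN and intensities are non-negative where present.
    """

    records: list[PhosphopeptideRecord]
    times: list[int]
    replicates: list[int]
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if sorted(self.times) != self.times or len(set(self.times)) != len(self.times):
            raise ValueError("time points must be strictly increasing")
        if 0 not in self.times:
            raise ValueError("baseline time point 0 is required")
        expected = [f"{t}min_rep{r}" for t in self.times for r in self.replicates]
        if list(self.intensities.columns) != expected:
            # normalize column order to (time asc, replicate asc)
            missing = set(expected) - set(self.intensities.columns)
            if missing:
                raise ValueError(f"missing intensity columns: {sorted(missing)}")
            self.intensities = self.intensities[expected]
        ids = [r.peptide_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide_id(s): {dupes}")
        if list(self.intensities.index) != ids:
            raise ValueError("intensity rows must align with records")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative intensity encountered")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def peptide_ids(self) -> list[str]:
        return [r.peptide_id for r in self.records]

    def sample_columns(self, time: int) -> list[str]:
        return [f"{time}min_rep{r}" for r in self.replicates]

    def subset(self, peptide_ids: list[str]) -> "QuantTable":
        keep = set(peptide_ids)
        recs = [r for r in self.records if r.peptide_id in keep]
        return QuantTable(
            records=recs,
            times=list(self.times),
            replicates=list(self.replicates),
            intensities=self.intensities.loc[[r.peptide_id for r in recs]],
        )


@dataclass
class ProteomeDb:
    """Protein id -> amino-acid sequence map (the motif background source)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"protein {pid}: empty sequence")
            odd = set(seq) - _AA20
            if odd:
                logger.warning("protein %s: non-standard letters %s", pid, sorted(odd))

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, pid: str) -> str:
        return self.sequences[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.sequences


@dataclass
class AnnotationTable:
    """GO annotations (gene_id, go_id, aspect, evidence_code), evidence-filtered."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "go_id", "aspect", "evidence_code"]))

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["gene_id", "go_id", "aspect"])
        if dup.any():
            self.table = self.table.loc[~dup].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def for_aspect(self, aspect: str) -> pd.DataFrame:
        return self.table[self.table["aspect"] == aspect]


@dataclass
class InteractionTable:
    """Curated kinase -> substrate interactions with kinase-family annotation."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["kinase_id", "substrate_id"])
        if dup.any():
            logger.warning("dropping %d duplicate interaction rows", int(dup.sum()))
            self.table = self.table.loc[~dup].reset_index(drop=True)
        self_loops = self.table["kinase_id"] == self.table["substrate_id"]
        if self_loops.any():
            logger.warning("%d self-loop interaction(s) present", int(self_loops.sum()))

    def __len__(self) -> int:
        return len(self.table)


def _parse_sites(text: str) -> list[tuple[int, str]]:
    sites = []
    for token in str(text).split(";"):
        token = token.strip()
        m = _SITE_TOKEN_RE.match(token)
        if not m:
            raise ValueError(f"malformed site token {token!r}")
        sites.append((int(m.group(2)), m.group(1)))
    return sites


def read_quant_table(
    path,
    proteome: ProteomeDb | None = None,
    column_map: dict[str, str] | None = None,
) -> QuantTable:
    """Read a quantified phosphopeptide TSV into a validated :class:`QuantTable`.

    Required columns: ``peptide_id, sequence, protein_id, sites, loc_prob``
    plus intensity columns named ``<time>min_rep<k>``. ``column_map`` renames
    non-standard headers to these names so Skyline-like exports can be adapted
    without code changes. If ``proteome`` is given, each site residue is
    validated against the protein sequence at its 1-based position.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "NA"],
                     keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    meta_cols = ["peptide_id", "sequence", "protein_id", "sites", "loc_prob"]
    missing_meta = [c for c in meta_cols if c not in df.columns]
    if missing_meta:
        raise ValueError(f"quant table missing columns: {missing_meta}")

    samples: list[tuple[int, int, str]] = []
    for col in df.columns:
        m = _INTENSITY_COL_RE.match(col)
        if m:
            samples.append((int(m.group(1)), int(m.group(2)), col))
    if not samples:
        raise ValueError("no intensity columns of the form '<time>min_rep<k>' found")
    times = sorted({t for t, _, _ in samples})
    reps = sorted({r for _, r, _ in samples})
    if 0 not in times:
        raise ValueError("baseline time point 0 is required ('0min_rep*' columns)")
    expected = {f"{t}min_rep{r}" for t in times for r in reps}
    present = {c for _, _, c in samples}
    if present != expected:
        raise ValueError(f"incomplete sample grid: missing {sorted(expected - present)}")

    records = []
    for idx, row in df.iterrows():
        try:
            sites = _parse_sites(row["sites"])
            probs = [float(x) for x in str(row["loc_prob"]).split(";")]
            rec = PhosphopeptideRecord(
                peptide_id=row["peptide_id"],
                sequence=row["sequence"],
                protein_id=row["protein_id"],
                sites=sites,
                loc_probability=probs,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {idx} ({row.get('peptide_id')!r}): {exc}") from exc
        if proteome is not None and rec.protein_id in proteome:
            pseq = proteome[rec.protein_id]
            for pos, res in rec.sites:
                if pos > len(pseq) or pseq[pos - 1] != res:
                    found = pseq[pos - 1] if pos <= len(pseq) else "<out of range>"
                    raise ValueError(
                        f"row {idx} ({rec.peptide_id!r}): site {res}{pos} does not match "
                        f"protein {rec.protein_id} residue {found!r} at position {pos}"
                    )
        records.append(rec)

    cols = [f"{t}min_rep{r}" for t in times for r in reps]
    intensities = df[cols].astype(float)
    intensities.index = pd.Index([r.peptide_id for r in records], name="peptide_id")
    return QuantTable(records=records, times=times, replicates=reps,
                      intensities=intensities)


def write_quant_table(table: QuantTable, path) -> None:
    """Write a QuantTable back to the canonical TSV layout (round-trip safe)."""
    rows = []
    for rec in table.records:
        rows.append({
            "peptide_id": rec.peptide_id,
            "sequence": rec.sequence,
            "protein_id": rec.protein_id,
            "sites": ";".join(f"{res}{pos}" for pos, res in rec.sites),
            "loc_prob": ";".join(repr(p) for p in rec.loc_probability),
        })
    meta = pd.DataFrame(rows)
    out = pd.concat([meta, table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_fasta(path) -> ProteomeDb:
    """Load a FASTA proteome; first whitespace token of the header is the id.

    Sequences are upper-cased. Duplicate ids keep the first record (warning).
    """
    sequences: dict[str, str] = {}
    n_dup = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in sequences:
            n_dup += 1
            continue
        sequences[pid] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    if n_dup:
        logger.warning("FASTA %s: %d duplicate id(s) dropped (keep-first)", path, n_dup)
    logger.info("loaded %d protein sequences from %s", len(sequences), path)
    return ProteomeDb(sequences=sequences)


def write_fasta(db: ProteomeDb, path) -> None:
    with open(path, "w") as fh:
        for pid, seq in db.sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_annotations(path, exclude_codes: frozenset[str] = frozenset({"IEA", "ND"})
                     ) -> AnnotationTable:
    """Read a GO annotation TSV, dropping excluded evidence codes.

    Evidence-code matching is case-insensitive; unknown aspect values are a
    row-level error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "go_id", "aspect", "evidence_code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    df["aspect"] = df["aspect"].str.upper()
    bad = ~df["aspect"].isin(_VALID_ASPECTS)
    if bad.any():
        idx = df.index[bad][0]
        raise ValueError(f"row {idx}: unknown aspect {df.loc[idx, 'aspect']!r}")
    codes_upper = {c.upper() for c in exclude_codes}
    df["evidence_code"] = df["evidence_code"].str.upper()
    keep = ~df["evidence_code"].isin(codes_upper)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d annotation rows with evidence in %s",
                    n_dropped, sorted(codes_upper))
    out = df.loc[keep, required].reset_index(drop=True)
    if out.empty:
        logger.warning("annotation table empty after evidence-code exclusion")
    return AnnotationTable(table=out)


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["kinase_id", "substrate_id", "kinase_family", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    if "site" not in df.columns:
        df["site"] = pd.NA
    return InteractionTable(table=df[required + ["site"]].reset_index(drop=True))


def write_graph(network: nx.DiGraph, path, fmt: str = "SIF") -> None:
    """Export a kinase-substrate graph as SIF or GraphML.

    SIF lines read ``kinase<TAB>phosphorylates<TAB>substrate``; GraphML keeps
    node attributes (family, identified_here, phosphorylated_here).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty graph")
    fmt = fmt.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v in network.edges():
                fh.write(f"{u}\tphosphorylates\t{v}\n")
    elif fmt == "GRAPHML":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r} (use SIF or GraphML)")
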