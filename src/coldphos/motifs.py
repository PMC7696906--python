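"""From-scratch motif-x: greedy extraction of over-represented phosphorylation
motifs from fixed-width site windows, motif-class grouping, and motif dynamics.

Windows are 13-mers centered on the phosphorylated S/T/Y (positions -6..+6),
padded with ``X`` where the protein terminus is closer than 6 residues. At
each greedy step the algorithm scores every candidate (position, residue) pair
by the binomial tail probability of seeing at least the observed number of
foreground windows with that residue at that position, given the background
frequency at that position; the most significant qualifying pair is fixed,
both window sets are restricted to matching windows, and the step repeats
until no pair passes. The accumulated constraints form one motif; its
foreground windows are removed and extraction restarts on the remainder.

S-, T- and Y-centered motifs are extracted independently, each with its own
minimum-occurrence threshold (30 for S, 20 for T and Y by convention) and a
step significance threshold of p < 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ProteomeDb, QuantTable

logger = logging.getLogger(__name__)

WINDOW_HALF = 6
WINDOW_LEN = 2 * WINDOW_HALF + 1
DEFAULT_MIN_OCC = {"S": 30, "T": 20, "Y": 20}
DEFAULT_P_THRESHOLD = 1e-6


@dataclass
class SiteWindow:
    """A 13-residue window around one phosphosite (positions -6..+6)."""

    peptide_id: str
    central: str
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LEN:
            raise ValueError(f"window must be {WINDOW_LEN} characters")
        if self.window[WINDOW_HALF] != self.central:
            raise ValueError("window center does not match the central residue")
        if self.central not in "STY":
            raise ValueError(f"central residue {self.central!r} not S/T/Y")


@dataclass
class MotifResult:
    """One extracted motif: ordered (offset, residue) constraints around the
    central residue, with extraction counts and the combined step score."""

    central: str
    constraints: list[tuple[int, str]]       # offsets in -6..+6 excluding 0
    fg_matches: int
    fg_size: int
    bg_matches: int
    bg_size: int
    score: float                              # -log10 product of step p-values
    step_pvalues: list[float] = field(default_factory=list)
    group: str = "other"

    @property
    def fold_enrichment(self) -> float:
        if self.bg_matches == 0 or self.fg_size == 0 or self.bg_size == 0:
            return np.inf
        return (self.fg_matches / self.fg_size) / (self.bg_matches / self.bg_size)

    def pattern(self) -> str:
        """Bracket-free pattern string, e.g. ``...R..S*......``."""
        chars = ["."] * WINDOW_LEN
        chars[WINDOW_HALF] = self.central
        for off, res in self.constraints:
            chars[WINDOW_HALF + off] = res
        return "".join(chars[:WINDOW_HALF + 1]) + "*" + "".join(chars[WINDOW_HALF + 1:])


def extract_window(sequence: str, position_1based: int,
                   half_width: int = WINDOW_HALF, peptide_id: str = "") -> SiteWindow:
    """Extract the +/-half_width window around a 1-based S/T/Y position,
    X-padded at the termini."""
    if not 1 <= position_1based <= len(sequence):
        raise ValueError(f"position {position_1based} outside sequence of "
                         f"length {len(sequence)}")
    central = sequence[position_1based - 1]
    if central not in "STY":
        raise ValueError(f"residue at position {position_1based} is "
                         f"{central!r}, not S/T/Y")
    start = position_1based - 1 - half_width
    end = position_1based + half_width
    left_pad = max(0, -start)
    right_pad = max(0, end - len(sequence))
    core = sequence[max(0, start):min(len(sequence), end)]
    window = "X" * left_pad + core + "X" * right_pad
    return SiteWindow(peptide_id=peptide_id, central=central, window=window)


def proteome_background_windows(proteome: ProteomeDb) -> list[SiteWindow]:
    """All S/T/Y-centered 13-mers of a proteome (the motif background)."""
    windows = []
    for pid, seq in proteome.sequences.items():
        for i, aa in enumerate(seq):
            if aa in "STY":
                windows.append(extract_window(seq, i + 1, peptide_id=pid))
    return windows


def peptide_site_windows(table: QuantTable, proteome: ProteomeDb
                         ) -> list[SiteWindow]:
    """One window per phosphosite of each peptide, cut from its protein.

    Multiply phosphorylated peptides contribute one window per site, each
    carrying the peptide's id (and hence its intensity profile downstream).
    """
    windows = []
    for rec in table.records:
        seq = proteome[rec.protein_id] if rec.protein_id in proteome else None
        for pos, res in rec.sites:
            if seq is not None:
                windows.append(extract_window(seq, pos, peptide_id=rec.peptide_id))
            else:
                logger.warning("peptide %s: protein %s not in proteome, skipped",
                               rec.peptide_id, rec.protein_id)
    return windows


def binomial_tail_p(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _window_matrix(windows: list[SiteWindow]) -> np.ndarray:
    return np.array([list(w.window) for w in windows]) if windows else \
        np.empty((0, WINDOW_LEN), dtype="<U1")


def match_motif(window: SiteWindow | str, motif: MotifResult) -> bool:
    """True iff the window satisfies every positional constraint and the
    central residue of the motif."""
    seq = window.window if isinstance(window, SiteWindow) else window
    if len(seq) != WINDOW_LEN:
        raise ValueError(f"window must be {WINDOW_LEN} characters")
    if seq[WINDOW_HALF] != motif.central:
        return False
    return all(seq[WINDOW_HALF + off] == res for off, res in motif.constraints)


def motifx(fg_windows: list[SiteWindow], bg_windows: list[SiteWindow],
           central: str, min_occ: int | None = None,
           p_threshold: float = DEFAULT_P_THRESHOLD) -> list[MotifResult]:
    """Greedy motif-x extraction for one central residue.

    Candidate (position, residue) pairs are scored by the binomial tail of
    the foreground count given the current background frequency at that
    position (recomputed after every restriction; a zero background frequency
    is replaced by the 1/(bg_size+1) pseudo-frequency). Ties are broken by
    larger fold enrichment, then smaller |offset|, then upstream first.
    """
    if central not in "STY":
        raise ValueError("central residue must be S, T or Y")
    if min_occ is None:
        min_occ = DEFAULT_MIN_OCC[central]
    fg = [w for w in fg_windows if w.central == central]
    bg = [w for w in bg_windows if w.central == central]
    if not bg:
        raise ValueError(f"no background windows with central residue {central}")
    bg_mat_full = _window_matrix(bg)
    bg_size_full = len(bg)
    fg_pool = _window_matrix(fg)
    fg_meta = list(fg)

    offsets = [o for o in range(-WINDOW_HALF, WINDOW_HALF + 1) if o != 0]
    motifs: list[MotifResult] = []

    while len(fg_pool) >= min_occ:
        cur_fg = fg_pool
        cur_bg = bg_mat_full
        constraints: list[tuple[int, str]] = []
        step_ps: list[float] = []
        while True:
            best = None
            n_fg = len(cur_fg)
            n_bg = len(cur_bg)
            if n_fg == 0 or n_bg == 0:
                break
            taken = {off for off, _ in constraints}
            for off in offsets:
                if off in taken:
                    continue
                col = WINDOW_HALF + off
                fg_col = cur_fg[:, col]
                bg_col = cur_bg[:, col]
                residues, counts = np.unique(fg_col, return_counts=True)
                for res, k in zip(residues, counts):
                    if res == "X" or k < min_occ:
                        continue
                    p0 = np.count_nonzero(bg_col == res) / n_bg
                    if p0 == 0.0:
                        p0 = 1.0 / (n_bg + 1)
                    p = binomial_tail_p(int(k), n_fg, p0)
                    if p >= p_threshold:
                        continue
                    fold = (k / n_fg) / p0
                    cand = (p, -fold, abs(off), off, res, int(k))
                    if best is None or cand < best:
                        best = cand
            if best is None:
                break
            p, _, _, off, res, k = best
            constraints.append((off, str(res)))
            step_ps.append(p)
            col = WINDOW_HALF + off
            cur_fg = cur_fg[cur_fg[:, col] == res]
            cur_bg = cur_bg[cur_bg[:, col] == res]
        if not constraints:
            break
        constraints.sort()
        motif = MotifResult(
            central=central, constraints=constraints,
            fg_matches=len(cur_fg), fg_size=len(fg_pool),
            bg_matches=int(np.count_nonzero(
                np.all(bg_mat_full[:, [WINDOW_HALF + o for o, _ in constraints]]
                       == [r for _, r in constraints], axis=1))),
            bg_size=bg_size_full,
            score=float(-np.sum(np.log10(step_ps))),
            step_pvalues=step_ps)
        motifs.append(motif)
        # remove matching fg windows; background stays full
        cols = [WINDOW_HALF + o for o, _ in constraints]
        vals = [r for _, r in constraints]
        matching = np.all(fg_pool[:, cols] == vals, axis=1)
        fg_pool = fg_pool[~matching]
        fg_meta = [w for w, m in zip(fg_meta, matching) if not m]
        logger.info("motif %s extracted (fg %d/%d, score %.1f)",
                    motif.pattern(), motif.fg_matches, motif.fg_size, motif.score)
    return motifs


# Kinase-recognition motif classes. Each entry: (class label, list of
# alternative constraint requirements); a motif belongs to the first class for
# which some alternative's constraints are all present. Checked in order.
DEFAULT_MOTIF_GROUPS: list[tuple[str, list[list[tuple[int, tuple[str, ...]]]]]] = [
    ("[LXR/KXXpS/pT] basic", [[(-5, ("L",)), (-3, ("R", "K"))]]),
    ("[R/KXXpS/pT] basic", [[(-3, ("R", "K"))]]),
    ("[pS/pTP] proline-directed", [[(1, ("P",))]]),
    ("[pS/pTXD/E] acidic", [[(2, ("D", "E"))]]),
    ("[pS/pTXXD/E] acidic", [[(3, ("D", "E"))]]),
    ("[SXpS]", [[(-2, ("S",))]]),
    ("[pS/pTF]", [[(1, ("F",))]]),
    ("[pS/pTG]", [[(1, ("G",))]]),
    ("[pSXP]", [[(2, ("P",))]]),
]


def group_motifs(motifs: list[MotifResult],
                 group_table=None) -> list[MotifResult]:
    """Attach a kinase-recognition class label to each motif ("other" if no
    class matches)."""
    table = DEFAULT_MOTIF_GROUPS if group_table is None else group_table
    for motif in motifs:
        cons = dict(motif.constraints)
        motif.group = "other"
        for label, alternatives in table:
            hit = any(all(cons.get(off) in residues for off, residues in alt)
                      for alt in alternatives)
            if hit:
                motif.group = label
                break
    return motifs


def motif_dynamics(dep_calls: pd.DataFrame, windows: list[SiteWindow],
                   motifs: list[MotifResult], table: QuantTable,
                   scheme: str = "time_vs_all") -> pd.DataFrame:
    """Per (motif group, time point) abundance and enrichment dynamics.

    The abundance track is the fold change of the mean intensity of the
    group's member peptides at time t vs 0 min. The enrichment p is a
    two-sided Fisher test of the 2x2 table [[a, b], [c, d]] where a/b count
    time-t DEPs matching / not matching the group and c/d count matching /
    non-matching peptides among DEPs pooled over all times
    (``scheme="time_vs_all"``); ``scheme="dep_vs_nondep"`` contrasts time-t
    DEPs against time-t non-DEPs instead.
    """
    if scheme not in ("time_vs_all", "dep_vs_nondep"):
        raise ValueError(f"unknown contingency scheme {scheme!r}")
    groups = sorted({m.group for m in motifs})
    members: dict[str, set[str]] = {g: set() for g in groups}
    for w in windows:
        for m in motifs:
            if match_motif(w, m):
                members[m.group].add(w.peptide_id)

    times = list(dep_calls.columns)
    dep_at = {t: set(dep_calls.index[dep_calls[t] != "none"]) for t in times}
    all_deps = set().union(*dep_at.values()) if times else set()
    base_cols = table.sample_columns(0)
    inten = table.intensities

    rows = []
    for g in groups:
        mem = members[g]
        mem_idx = [pid for pid in inten.index if pid in mem]
        base_mean = np.nan
        if mem_idx:
            base_mean = float(np.nanmean(inten.loc[mem_idx, base_cols].to_numpy()))
        for t in times:
            cols = table.sample_columns(t)
            fold = np.nan
            if mem_idx and base_mean and np.isfinite(base_mean):
                t_mean = float(np.nanmean(inten.loc[mem_idx, cols].to_numpy()))
                fold = t_mean / base_mean
            deps_t = dep_at[t]
            if not deps_t:
                rows.append({"group": g, "time": t, "fold_change": fold,
                             "n_members": len(mem), "p_value": np.nan})
                continue
            a = len(deps_t & mem)
            b = len(deps_t) - a
            if scheme == "time_vs_all":
                c = len(all_deps & mem)
                d = len(all_deps) - c
            else:
                non_deps = set(dep_calls.index) - deps_t
                c = len(non_deps & mem)
                d = len(non_deps) - c
            p = float(stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")[1])
            rows.append({"group": g, "time": t, "fold_change": fold,
                         "n_members": len(mem), "p_value": p})
    return pd.DataFrame(rows)
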