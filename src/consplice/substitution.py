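"""Splice-aware substitution probability model.

Every scored genic site is assigned a summed splice-prediction score
(AG+AL+DG+DL for one ref->alt substitution; the max over the three possible
substitutions when the site carries no variant) and an 8-way score bin. Sites
are tallied by (reference allele x score bin) into a 4x8 matrix of
variant-bearing vs variant-free counts, from which per-cell substitution
probabilities and genome-wide cell proportions are derived. Autosome and X
are tallied into separate matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AUTOSOME, REF_ALLELES, REF_INDEX

DEFAULT_BIN_EDGES = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 4.0)
SCORE_MAX = 4.0


def sum_delta_scores(ag: float, al: float, dg: float, dl: float) -> float:
    """Summed splice score for one ref->alt substitution (in [0, 4])."""
    total = float(ag) + float(al) + float(dg) + float(dl)
    if not (0.0 <= total <= SCORE_MAX + 1e-9):
        raise ValueError(f"summed delta score {total} outside [0, 4]")
    return min(total, SCORE_MAX)


@dataclass(frozen=True)
class ScoreBinning:
    """Half-open partition of the summed-score range [0, 4].

    The last interval is closed so a summed score of exactly 4.0 falls in the
    top bin. Default is 8 bins, finer at low scores where most sites lie; the
    splicing-unaware model uses a single [0, 4] bin.
    """

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("binning needs at least two edges")
        if e[0] != 0.0 or e[-1] != SCORE_MAX or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must increase from 0.0 to 4.0")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def index(self, score):
        """Bin index for a score or array of scores in [0, 4]."""
        s = np.asarray(score, dtype=float)
        if np.any((s < 0) | (s > SCORE_MAX)):
            raise ValueError("score outside [0, 4]")
        idx = np.searchsorted(self.edges, s, side="right") - 1
        idx = np.clip(idx, 0, self.n_bins - 1)
        return idx if s.ndim else int(idx)

    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0


SPLICING_UNAWARE_BINNING = ScoreBinning(edges=(0.0, SCORE_MAX))


@dataclass
class ChromScores:
    """Per-chromosome score track: one row per scored site (<=3 alts each)."""

    pos: np.ndarray        # sorted 0-based positions, shape (n,)
    ref_idx: np.ndarray    # index into ACGT, shape (n,)
    alt_idx: np.ndarray    # (n, 3) int8, -1 where fewer than 3 alts recorded
    sums: np.ndarray       # (n, 3) summed scores, NaN where no alt
    max_sum: np.ndarray    # (n,)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def locate(self, pos) -> np.ndarray:
        """Row indices for positions; -1 where the position is unscored."""
        p = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if len(self.pos) == 0:
            return np.full(len(p), -1, dtype=np.int64)
        idx = np.searchsorted(self.pos, p)
        idx[idx >= len(self.pos)] = -1
        miss = self.pos[idx] != p
        idx[miss] = -1
        return idx


class SiteScoreTable:
    """All per-site, per-alt splice-prediction scores, indexed by chromosome."""

    def __init__(self, chroms: dict[str, ChromScores]):
        self._chroms = chroms

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def chrom(self, name: str) -> ChromScores:
        return self._chroms[name]

    def has_chrom(self, name: str) -> bool:
        return name in self._chroms

    @property
    def n_sites(self) -> int:
        return sum(c.n_sites for c in self._chroms.values())

    @classmethod
    def from_records(cls, df: pd.DataFrame) -> "SiteScoreTable":
        """Build from a long table: chrom, pos (0-based), ref, alt, ag, al, dg, dl."""
        req = {"chrom", "pos", "ref", "alt", "ag", "al", "dg", "dl"}
        if not req.issubset(df.columns):
            raise ValueError(f"score records need columns {sorted(req)}")
        deltas = df[["ag", "al", "dg", "dl"]].to_numpy(dtype=float)
        if np.any((deltas < 0) | (deltas > 1)) or not np.all(np.isfinite(deltas)):
            raise ValueError("delta scores must be finite and in [0, 1]")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("ref == alt in score records")
        chroms: dict[str, ChromScores] = {}
        sums_all = deltas.sum(axis=1)
        df = df.assign(_sum=np.minimum(sums_all, SCORE_MAX))
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values(["pos", "alt"], kind="mergesort")
            pos_all = sub["pos"].to_numpy(dtype=np.int64)
            upos, inv = np.unique(pos_all, return_inverse=True)
            n = len(upos)
            ref_codes = sub["ref"].map(REF_INDEX)
            if ref_codes.isna().any():
                raise ValueError("reference allele outside ACGT")
            ref_arr = ref_codes.to_numpy(dtype=np.int8)
            ref_idx = np.full(n, -1, dtype=np.int8)
            ref_idx[inv] = ref_arr
            mn = np.full(n, np.int8(127))
            mx = np.full(n, np.int8(-1))
            np.minimum.at(mn, inv, ref_arr)
            np.maximum.at(mx, inv, ref_arr)
            if np.any(mn != mx):
                bad = upos[np.nonzero(mn != mx)[0][0]]
                raise ValueError(f"inconsistent reference allele at {chrom}:{bad}")
            slot = sub.groupby("pos").cumcount().to_numpy()
            if slot.max(initial=0) > 2:
                raise ValueError("more than 3 alternate alleles at one site")
            alt_codes = sub["alt"].map(REF_INDEX)
            if alt_codes.isna().any():
                raise ValueError("alternate allele outside ACGT")
            alt_idx = np.full((n, 3), -1, dtype=np.int8)
            sums = np.full((n, 3), np.nan)
            alt_idx[inv, slot] = alt_codes.to_numpy(dtype=np.int8)
            sums[inv, slot] = sub["_sum"].to_numpy()
            chroms[str(chrom)] = ChromScores(
                pos=upos,
                ref_idx=ref_idx,
                alt_idx=alt_idx,
                sums=sums,
                max_sum=np.nanmax(sums, axis=1),
            )
        return cls(chroms)

    def summed_score(self, chrom: str, pos: int, alt: str) -> float | None:
        """Variant-specific summed score; None when the site/alt is unscored."""
        if chrom not in self._chroms:
            return None
        cs = self._chroms[chrom]
        i = int(cs.locate(pos)[0])
        if i < 0:
            return None
        a = REF_INDEX.get(alt)
        if a is None:
            return None
        hit = np.nonzero(cs.alt_idx[i] == a)[0]
        return float(cs.sums[i, hit[0]]) if len(hit) else None

    def max_summed(self, chrom: str, pos: int) -> float | None:
        if chrom not in self._chroms:
            return None
        cs = self._chroms[chrom]
        i = int(cs.locate(pos)[0])
        return float(cs.max_sum[i]) if i >= 0 else None


def site_bin(
    table: SiteScoreTable,
    chrom: str,
    pos: int,
    alt: str | None,
    binning: ScoreBinning,
) -> tuple[float, int] | None:
    """Summed score and bin for a site.

    Without a variant the max summed score across the site's alternates is
    used; with a variant, the score of that specific ref->alt substitution.
    Returns None when the site (or alt) has no score record.
    """
    score = table.max_summed(chrom, pos) if alt is None else table.summed_score(chrom, pos, alt)
    if score is None or np.isnan(score):
        return None
    return score, binning.index(score)


@dataclass
class SubstitutionCountMatrix:
    """(ref allele x score bin) tallies of variant-bearing vs variant-free sites."""

    n_var: np.ndarray     # (4, n_bins) int64
    n_novar: np.ndarray   # (4, n_bins) int64
    binning: ScoreBinning
    chrom_class: str = AUTOSOME
    skipped_variants: int = 0   # variants at sites outside the processed set

    @property
    def total_sites(self) -> int:
        return int(self.n_var.sum() + self.n_novar.sum())

    def __add__(self, other: "SubstitutionCountMatrix") -> "SubstitutionCountMatrix":
        if other.binning.edges != self.binning.edges or other.chrom_class != self.chrom_class:
            raise ValueError("incompatible matrices")
        return SubstitutionCountMatrix(
            n_var=self.n_var + other.n_var,
            n_novar=self.n_novar + other.n_novar,
            binning=self.binning,
            chrom_class=self.chrom_class,
            skipped_variants=self.skipped_variants + other.skipped_variants,
        )


def accumulate_counts(
    scores: SiteScoreTable,
    site_index: dict[str, np.ndarray],
    variants: pd.DataFrame,
    binning: ScoreBinning,
    chrom_class: str = AUTOSOME,
) -> SubstitutionCountMatrix:
    """Tally processed sites into the (ref, bin) count matrix.

    ``site_index`` selects, per chromosome, the rows of the score table that
    lie in merged protein-coding sequence of the given chromosome class and
    survived masking/coverage. Each selected site contributes once: to n_var
    (binned by its variant's specific summed score) when a retained variant
    falls on it, otherwise to n_novar (binned by the max summed score). When
    several alternates of one site are retained the largest variant-specific
    sum is used, so the site is still counted once.
    """
    nb = binning.n_bins
    n_var = np.zeros((4, nb), dtype=np.int64)
    n_novar = np.zeros((4, nb), dtype=np.int64)
    skipped = 0

    for chrom, idx in site_index.items():
        cs = scores.chrom(chrom)
        idx = np.asarray(idx, dtype=np.int64)
        processed = np.zeros(cs.n_sites, dtype=bool)
        processed[idx] = True

        var_sum = np.full(cs.n_sites, np.nan)
        sub = variants[variants["chrom"] == chrom]
        if len(sub):
            vpos = sub["pos"].to_numpy(dtype=np.int64)
            valt = sub["alt"].map(REF_INDEX).to_numpy(dtype=np.int8)
            rows = cs.locate(vpos)
            ok = (rows >= 0) & processed[np.clip(rows, 0, None)]
            skipped += int((~ok).sum())
            rows, valt = rows[ok], valt[ok]
            match = cs.alt_idx[rows] == valt[:, None]
            has = match.any(axis=1)
            skipped += int((~has).sum())
            rows, match = rows[has], match[has]
            vsums = cs.sums[rows][match]
            np.fmax.at(var_sum, rows, vsums)

        sel_var = ~np.isnan(var_sum[idx])
        vi = idx[sel_var]
        ni = idx[~sel_var]
        if len(vi):
            cells = cs.ref_idx[vi] * nb + binning.index(var_sum[vi])
            np.add.at(n_var.reshape(-1), cells, 1)
        if len(ni):
            cells = cs.ref_idx[ni] * nb + binning.index(cs.max_sum[ni])
            np.add.at(n_novar.reshape(-1), cells, 1)

    return SubstitutionCountMatrix(
        n_var=n_var, n_novar=n_novar, binning=binning,
        chrom_class=chrom_class, skipped_variants=skipped,
    )


@dataclass
class SubstitutionProbabilityTable:
    """Per-cell substitution probabilities and genome-wide cell proportions."""

    p: np.ndarray            # (4, n_bins)
    proportion: np.ndarray   # (4, n_bins), sums to 1
    n_var: np.ndarray
    n_novar: np.ndarray
    binning: ScoreBinning
    chrom_class: str = AUTOSOME
    empty_cells: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_cells(self) -> int:
        return self.p.size

    def to_frame(self) -> pd.DataFrame:
        nb = self.binning.n_bins
        edges = self.binning.edges
        rows = []
        for r, ref in enumerate(REF_ALLELES):
            for b in range(nb):
                rows.append(
                    {
                        "chrom_class": self.chrom_class,
                        "ref": ref,
                        "bin_lo": edges[b],
                        "bin_hi": edges[b + 1],
                        "n_var": int(self.n_var[r, b]),
                        "n_novar": int(self.n_novar[r, b]),
                        "p": self.p[r, b],
                        "proportion": self.proportion[r, b],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SubstitutionProbabilityTable":
        df = pd.read_csv(path, sep="\t")
        classes = df["chrom_class"].unique()
        if len(classes) != 1:
            raise ValueError("one chromosome class per table file")
        edges = sorted(set(df["bin_lo"]) | set(df["bin_hi"]))
        binning = ScoreBinning(edges=tuple(edges))
        nb = binning.n_bins
        p = np.zeros((4, nb))
        prop = np.zeros((4, nb))
        nv = np.zeros((4, nb), dtype=np.int64)
        nn = np.zeros((4, nb), dtype=np.int64)
        for _, row in df.iterrows():
            r = REF_INDEX[row["ref"]]
            b = binning.index(min((row["bin_lo"] + row["bin_hi"]) / 2, SCORE_MAX))
            p[r, b] = row["p"]
            prop[r, b] = row["proportion"]
            nv[r, b] = row["n_var"]
            nn[r, b] = row["n_novar"]
        return cls(
            p=p, proportion=prop, n_var=nv, n_novar=nn,
            binning=binning, chrom_class=str(classes[0]),
            empty_cells=(nv + nn) == 0,
        )


def compute_probability_table(matrix: SubstitutionCountMatrix) -> SubstitutionProbabilityTable:
    """Derive p(ref, bin) and Proportion(ref, bin) from the count matrix.

    p is the fraction of the cell's sites bearing a retained variant; cells
    with no sites get p = 0 and are flagged (downstream O/E pseudocounts
    absorb the degeneracy). Proportion is the cell's share of all processed
    sites and sums to 1 over the matrix.
    """
    totals = matrix.n_var + matrix.n_novar
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no sites tallied; cannot form probabilities")
    empty = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(empty, 0.0, matrix.n_var / np.where(empty, 1, totals))
    proportion = totals / grand
    return SubstitutionProbabilityTable(
        p=p,
        proportion=proportion,
        n_var=matrix.n_var.copy(),
        n_novar=matrix.n_novar.copy(),
        binning=matrix.binning,
        chrom_class=matrix.chrom_class,
        empty_cells=empty,
    )
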