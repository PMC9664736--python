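"""Regional splicing-constraint model.

Genes are tiled into windows (or treated whole), each window accumulates
observed retained-variant counts and model-expected counts in the 32
(ref allele x score bin) cells, and a likelihood-weighted, pseudocounted
observed/expected statistic

    sum_i  X[i] * (O[i] - E[i]) / E[i],    O[i] = 1 + O_raw[i], E[i] = 1 + E_raw[i]

is computed per window. The pseudocounts center the null at 0 with an
unbounded negative limit, so stronger constraint (fewer splice-relevant
variants observed than expected) is a more negative raw value. Windows with
too few informative sites or too little score coverage are dropped, raw
values are rank-normalized to [0, 1] with 1.0 the most constrained region,
and autosome and X are modeled separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .genome import AUTOSOME, GeneModel, GenomeConfig, interval_overlap
from .substitution import (
    ScoreBinning,
    SiteScoreTable,
    SubstitutionProbabilityTable,
    accumulate_counts,
    compute_probability_table,
    SPLICING_UNAWARE_BINNING,
)

logger = logging.getLogger(__name__)

#: Critical value for the minimum number of informative sites per window,
#: from an F-distribution table at alpha = 0.025 (carried as a constant; see
#: docs for why it is not recomputed at runtime).
INFORMATIVE_SITE_CUTOFF = 6.5415

DEFAULT_MIN_WINDOW = 50
DEFAULT_MIN_COVERAGE_FRACTION = 0.8

WEIGHT_SCHEMES = (
    "unweighted",
    "linear",
    "log",
    "one-minus-proportion",
    "inverse-proportion",
    "inverse-substitution-rate",
)


@dataclass(frozen=True)
class WindowFilterConfig:
    """Thresholds for retaining a window in the constraint model."""

    min_informative: float = INFORMATIVE_SITE_CUTOFF
    min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION
    min_window_size: int = DEFAULT_MIN_WINDOW
    informative_rate: float | None = None  # Poisson rate: genome-wide P(score > 0)

    def __post_init__(self) -> None:
        if self.min_informative <= 0 or self.min_coverage_fraction <= 0 or self.min_window_size <= 0:
            raise ValueError("window filter thresholds must be positive")


@dataclass
class ConstraintRegion:
    """A genomic window with per-cell observed/expected tallies."""

    region_id: str
    chrom: str
    start: int
    end: int
    gene_ids: tuple[str, ...]
    chrom_class: str
    o_raw: np.ndarray | None = None   # (4, n_bins) observed retained variants
    e_raw: np.ndarray | None = None   # (4, n_bins) summed per-site expectations
    n_informative: int = 0
    coverage_fraction: float = 0.0
    raw_oe: float = float("nan")
    score: float = float("nan")
    in_single_exon_gene: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.region_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


def weight_vector(
    scheme: str,
    table: SubstitutionProbabilityTable,
) -> np.ndarray:
    """Per-cell likelihood weights X[i], shape (4, n_bins).

    unweighted -> 1; linear -> the bin's midpoint summed score; log ->
    -10*log10(Proportion); one-minus-proportion -> 1 - Proportion;
    inverse-proportion -> 1/Proportion; inverse-substitution-rate -> 1/p.
    Inverse and log schemes set cells with a zero denominator to weight 0
    (flagged via log) so empty cells contribute nothing.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")
    prop = table.proportion
    shape = prop.shape
    if scheme == "unweighted":
        return np.ones(shape)
    if scheme == "linear":
        return np.broadcast_to(table.binning.midpoints(), shape).copy()
    zero_prop = prop <= 0
    if scheme == "log":
        with np.errstate(divide="ignore"):
            w = np.where(zero_prop, 0.0, -10.0 * np.log10(np.where(zero_prop, 1.0, prop)))
        w = np.clip(w, 0.0, None)
    elif scheme == "one-minus-proportion":
        w = 1.0 - prop
    elif scheme == "inverse-proportion":
        w = np.where(zero_prop, 0.0, 1.0 / np.where(zero_prop, 1.0, prop))
    else:  # inverse-substitution-rate
        zero_p = table.p <= 0
        w = np.where(zero_p, 0.0, 1.0 / np.where(zero_p, 1.0, table.p))
        zero_prop = zero_p
    if zero_prop.any():
        logger.warning("%d cells received weight 0 under scheme %s", int(zero_prop.sum()), scheme)
    return w


def weighted_oe(o_raw: np.ndarray, e_raw: np.ndarray, weights: np.ndarray) -> float:
    """Pseudocounted, weighted O/E statistic for one region.

    Each cell's observed and expected counts default to 1.0 before the raw
    tallies are added, so a region with O_raw = E_raw everywhere scores
    exactly 0 under any weight scheme.
    """
    o = 1.0 + np.asarray(o_raw, dtype=float)
    e = 1.0 + np.asarray(e_raw, dtype=float)
    return float(np.sum(np.asarray(weights, dtype=float) * (o - e) / e))


def log_display_score(score: float, cap: float = 60.0) -> float:
    """Display transform -10*log10(1 - score); a score of 1.0 maps to ``cap``."""
    if not (0.0 <= score <= 1.0):
        raise ValueError("constraint score outside [0, 1]")
    if score == 1.0:
        return cap
    return min(-10.0 * np.log10(1.0 - score), cap)


def enumerate_windows(
    genes: list[GeneModel],
    genome: GenomeConfig,
    window_size: int = DEFAULT_MIN_WINDOW,
    step: int | None = None,
    mode: str = "windowed",
    min_window_size: int = DEFAULT_MIN_WINDOW,
) -> list[ConstraintRegion]:
    """Tile merged gene spans into windows, or emit one region per gene.

    Windows start at the 5'-most base of each merged gene interval and move in
    ``step`` increments (default: non-overlapping, step = window size); a
    trailing window is clipped at the interval end. On X, regions overlapping
    a pseudoautosomal interval are dropped. Chromosomes with no model class
    (e.g. Y) are skipped.
    """
    if mode not in ("windowed", "per-gene"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "windowed":
        if window_size < min_window_size:
            raise ValueError(
                f"window_size {window_size} is below the minimum {min_window_size} bp "
                f"required for the informative-site cutoff ({INFORMATIVE_SITE_CUTOFF})"
            )
        step = window_size if step is None else step
        if step < 1 or step > window_size:
            raise ValueError("step must be in [1, window_size]")

    regions: list[ConstraintRegion] = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
        cls = genome.chromosome_class(gene.chrom)
        if cls is None:
            continue
        pars = genome.pars_for(gene.chrom)
        if mode == "per-gene":
            bounds = [gene.span]
        else:
            bounds = []
            for s, e in gene.merged_intervals:
                start = s
                while start < e:
                    bounds.append((start, min(start + window_size, e)))
                    start += step
        for s, e in bounds:
            if any(interval_overlap((s, e), p) for p in pars):
                continue
            regions.append(
                ConstraintRegion(
                    region_id=f"{gene.chrom}:{s}-{e}:{gene.gene_id}",
                    chrom=gene.chrom,
                    start=s,
                    end=e,
                    gene_ids=(gene.gene_id,),
                    chrom_class=cls,
                    in_single_exon_gene=gene.single_exon,
                )
            )
    return regions


@dataclass
class SiteData:
    """Per-chromosome processed-site arrays used for region tallies."""

    pos: np.ndarray          # processed (scored, in-gene, unmasked) sites, sorted
    cell: np.ndarray         # (ref, bin) flat cell per site
    p: np.ndarray            # per-site substitution probability
    site_score: np.ndarray   # summed score used for the site (variant-specific if any)
    var_pos: np.ndarray      # retained variant positions (may repeat per site)
    var_cell: np.ndarray     # the variant's (ref, bin) cell
    n_bins: int = 8


def prepare_site_data(
    scores: SiteScoreTable,
    site_index: dict[str, np.ndarray],
    variants: pd.DataFrame,
    binning: ScoreBinning,
    table: SubstitutionProbabilityTable,
) -> dict[str, SiteData]:
    """Assign every processed site its cell, probability, and effective score."""
    from .genome import REF_INDEX

    nb = binning.n_bins
    out: dict[str, SiteData] = {}
    for chrom, idx in site_index.items():
        cs = scores.chrom(chrom)
        idx = np.sort(np.asarray(idx, dtype=np.int64))
        processed = np.zeros(cs.n_sites, dtype=bool)
        processed[idx] = True

        var_sum = np.full(cs.n_sites, np.nan)
        vpos_list = []
        vcell_list = []
        sub = variants[variants["chrom"] == chrom]
        if len(sub):
            vpos = sub["pos"].to_numpy(dtype=np.int64)
            valt = sub["alt"].map(REF_INDEX).to_numpy(dtype=np.int8)
            rows = cs.locate(vpos)
            ok = (rows >= 0) & processed[np.clip(rows, 0, None)]
            rows_ok, valt_ok, vpos_ok = rows[ok], valt[ok], vpos[ok]
            match = cs.alt_idx[rows_ok] == valt_ok[:, None]
            has = match.any(axis=1)
            rows_ok, vpos_ok = rows_ok[has], vpos_ok[has]
            vsums = cs.sums[rows_ok][match[has]]
            np.fmax.at(var_sum, rows_ok, vsums)
            vcell = cs.ref_idx[rows_ok].astype(np.int64) * nb + binning.index(vsums)
            order = np.argsort(vpos_ok, kind="mergesort")
            vpos_list, vcell_list = vpos_ok[order], vcell[order]

        eff_score = np.where(np.isnan(var_sum[idx]), cs.max_sum[idx], var_sum[idx])
        cell = cs.ref_idx[idx].astype(np.int64) * nb + binning.index(eff_score)
        out[chrom] = SiteData(
            pos=cs.pos[idx],
            cell=cell,
            p=table.p.reshape(-1)[cell],
            site_score=eff_score,
            var_pos=np.asarray(vpos_list, dtype=np.int64),
            var_cell=np.asarray(vcell_list, dtype=np.int64),
            n_bins=nb,
        )
    return out


def tally_regions(regions: list[ConstraintRegion], site_data: dict[str, SiteData]) -> None:
    """Fill each region's O_raw/E_raw, informative count, and coverage in place."""
    for region in regions:
        sd = site_data.get(region.chrom)
        if sd is None:
            raise ValueError(f"no site data for chromosome {region.chrom}")
        lo = int(np.searchsorted(sd.pos, region.start))
        hi = int(np.searchsorted(sd.pos, region.end))
        cells = sd.cell[lo:hi]
        vlo = int(np.searchsorted(sd.var_pos, region.start))
        vhi = int(np.searchsorted(sd.var_pos, region.end))
        nb = sd.n_bins
        e = np.bincount(cells, weights=sd.p[lo:hi], minlength=4 * nb).reshape(4, nb)
        o = np.bincount(sd.var_cell[vlo:vhi], minlength=4 * nb).reshape(4, nb)
        region.e_raw = e
        region.o_raw = o.astype(np.int64)
        region.n_informative = int(np.count_nonzero(sd.site_score[lo:hi] > 0.0))
        region.coverage_fraction = (hi - lo) / region.length


def filter_windows(
    regions: list[ConstraintRegion],
    config: WindowFilterConfig,
) -> list[ConstraintRegion]:
    """Drop windows below the informative-site cutoff or score coverage floor.

    Also validates, when the genome-wide informative rate (Poisson lambda) is
    known, that the configured window size is expected to clear the cutoff;
    a warning is logged otherwise.
    """
    if config.informative_rate is not None:
        expected = config.informative_rate * config.min_window_size
        if expected < config.min_informative:
            logger.warning(
                "expected informative sites per %d bp window (%.2f) below cutoff %.4f",
                config.min_window_size, expected, config.min_informative,
            )
    return [
        r
        for r in regions
        if r.n_informative >= config.min_informative
        and r.coverage_fraction >= config.min_coverage_fraction
    ]


def adjust_single_exon_genes(
    regions: list[ConstraintRegion],
    delta: float | str = "auto",
) -> list[ConstraintRegion]:
    """Shift raw O/E of regions inside single-exon genes in the positive direction.

    Single-exon genes do not splice, so their depletion signal is not
    splicing constraint; their raw O/E is pushed toward the tolerant end.
    ``delta='auto'`` moves the single-exon mean to the 80th percentile of the
    multi-exon raw O/E distribution (never negative); a float applies a fixed
    shift.
    """
    single = [r for r in regions if r.in_single_exon_gene]
    if not single:
        return regions
    if delta == "auto":
        multi = [r.raw_oe for r in regions if not r.in_single_exon_gene]
        if not multi:
            d = 0.0
        else:
            d = max(0.0, float(np.percentile(multi, 80)) - float(np.mean([r.raw_oe for r in single])))
    else:
        d = float(delta)
    for r in single:
        r.raw_oe += d
    return regions


def normalize_scores(regions: list[ConstraintRegion]) -> list[ConstraintRegion]:
    """Rank-normalize raw O/E to [0, 1]: smallest raw O/E -> 1.0 (most constrained).

    Scores are (descending-sort rank)/(n-1); ties get the mean of their ranks.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to normalize")
    oe = np.array([r.raw_oe for r in regions])
    if np.any(~np.isfinite(oe)):
        raise ValueError("raw O/E not computed for all regions")
    ranks = rankdata(oe, method="average")  # ascending: smallest O/E -> rank 1
    scores = (len(regions) - ranks) / (len(regions) - 1)
    for r, s in zip(regions, scores):
        r.score = float(s)
    return regions


class RegionIndex:
    """Position -> constraint score lookup over retained regions of one class."""

    def __init__(self, regions: list[ConstraintRegion]):
        self.regions = regions
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        self._regions_by_chrom: dict[str, list[ConstraintRegion]] = {}
        for r in regions:
            self._regions_by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in self._regions_by_chrom.items():
            rs.sort(key=lambda r: r.start)
            self._by_chrom[chrom] = (
                np.array([r.start for r in rs]),
                np.array([r.end for r in rs]),
                np.array([r.score for r in rs]),
                np.array([r.length for r in rs]),
            )

    def score_position(self, chrom: str, pos: int) -> float:
        """Max score over retained regions covering the position; NaN if none."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return float("nan")
        starts, ends, scores, lengths = entry
        hi = int(np.searchsorted(starts, pos, side="right"))
        max_len = int(lengths.max(initial=1))
        lo = int(np.searchsorted(starts, pos - max_len))
        cover = (ends[lo:hi] > pos)
        if not cover.any():
            return float("nan")
        return float(scores[lo:hi][cover].max())

    def region_id_at(self, chrom: str, pos: int) -> str | None:
        """Region id of the best-scoring retained region covering the position."""
        rs = self._regions_by_chrom.get(chrom)
        if rs is None:
            return None
        entry = self._by_chrom[chrom]
        starts, _, _, lengths = entry
        hi = int(np.searchsorted(starts, pos, side="right"))
        lo = int(np.searchsorted(starts, pos - int(lengths.max(initial=1))))
        best, best_score = None, -np.inf
        for r in rs[lo:hi]:
            if r.start <= pos < r.end and r.score > best_score:
                best, best_score = r.region_id, r.score
        return best


def regions_to_frame(regions: list[ConstraintRegion]) -> pd.DataFrame:
    """BED-compatible TSV frame of scored regions."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "region_id": [r.region_id for r in regions],
            "genes": [",".join(r.gene_ids) for r in regions],
            "raw_OE": [r.raw_oe for r in regions],
            "constraint_score": [r.score for r in regions],
            "n_informative": [r.n_informative for r in regions],
            "coverage_fraction": [r.coverage_fraction for r in regions],
            "chrom_class": [r.chrom_class for r in regions],
        }
    )


def regions_from_frame(df: pd.DataFrame) -> list[ConstraintRegion]:
    """Rebuild scored regions from a saved regions TSV frame."""
    regions = []
    for row in df.itertuples(index=False):
        r = ConstraintRegion(
            region_id=str(row.region_id),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            gene_ids=tuple(str(row.genes).split(",")),
            chrom_class=str(getattr(row, "chrom_class", AUTOSOME)),
        )
        r.raw_oe = float(row.raw_OE)
        r.score = float(row.constraint_score)
        r.n_informative = int(row.n_informative)
        r.coverage_fraction = float(row.coverage_fraction)
        regions.append(r)
    return regions


class RegionsModel:
    """Score lookup over a persisted regions table (duck-types the estimator)."""

    def __init__(self, regions: list[ConstraintRegion]):
        self._index = RegionIndex(regions)
        self.regions = regions

    @classmethod
    def from_tsv(cls, path) -> "RegionsModel":
        return cls(regions_from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str})))

    def score_position(self, chrom: str, pos: int) -> float:
        return self._index.score_position(chrom, pos)

    def region_id_at(self, chrom: str, pos: int) -> str | None:
        return self._index.region_id_at(chrom, pos)


class SplicingConstraintModel(BaseEstimator):
    """Estimator producing regional splicing-constraint scores.

    Parameters
    ----------
    window_size, step : window tiling of merged gene spans; ``step=None``
        means non-overlapping tiling. ``mode='per-gene'`` scores whole genes.
    weight_scheme : one of ``WEIGHT_SCHEMES``; 1/Proportion is the default
        (the best-performing weighting).
    bin_edges : summed-score bin edges (8 bins over [0, 4] by default).
    min_informative, min_coverage_fraction : window retention thresholds.
    single_exon_delta : 'auto' or a fixed positive shift for single-exon genes.
    splicing_aware : when False, a single [0, 4] bin with unweighted scheme
        reproduces the splicing-unaware constraint model.

    Fitted attributes (per chromosome class 'autosome'/'X'):
    ``tables_``, ``weights_``, ``regions_``, ``index_``, ``lambda_``.
    """

    def __init__(
        self,
        window_size: int = DEFAULT_MIN_WINDOW,
        step: int | None = None,
        mode: str = "windowed",
        weight_scheme: str = "inverse-proportion",
        bin_edges: tuple[float, ...] = None,
        min_informative: float = INFORMATIVE_SITE_CUTOFF,
        min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
        single_exon_delta: float | str = "auto",
        splicing_aware: bool = True,
    ):
        self.window_size = window_size
        self.step = step
        self.mode = mode
        self.weight_scheme = weight_scheme
        self.bin_edges = bin_edges
        self.min_informative = min_informative
        self.min_coverage_fraction = min_coverage_fraction
        self.single_exon_delta = single_exon_delta
        self.splicing_aware = splicing_aware

    # -- pipeline ---------------------------------------------------------

    def _binning(self) -> ScoreBinning:
        if not self.splicing_aware:
            return SPLICING_UNAWARE_BINNING
        if self.bin_edges is None:
            return ScoreBinning()
        return ScoreBinning(edges=tuple(self.bin_edges))

    def _scheme(self) -> str:
        return "unweighted" if not self.splicing_aware else self.weight_scheme

    def fit(self, data, y=None):
        """Fit from a mapping with keys genes, scores, variants, genome, site_index.

        ``genes`` is a list of GeneModel, ``scores`` a SiteScoreTable,
        ``variants`` the filtered population-variant DataFrame, ``genome`` a
        GenomeConfig and ``site_index`` the per-chromosome processed-site rows
        (as produced by :func:`consplice.io.select_model_sites`).
        """
        genes: list[GeneModel] = data["genes"]
        scores: SiteScoreTable = data["scores"]
        variants: pd.DataFrame = data["variants"]
        genome: GenomeConfig = data["genome"]
        site_index: dict[str, np.ndarray] = data["site_index"]

        binning = self._binning()
        scheme = self._scheme()
        self.binning_ = binning
        self.tables_ = {}
        self.weights_ = {}
        self.regions_ = {}
        self.index_ = {}
        self.lambda_ = {}

        classes = sorted({genome.chromosome_class(c) for c in site_index} - {None})
        for cls in classes:
            cls_index = {
                c: ix for c, ix in site_index.items() if genome.chromosome_class(c) == cls
            }
            cls_genes = [g for g in genes if genome.chromosome_class(g.chrom) == cls]
            matrix = accumulate_counts(scores, cls_index, variants, binning, cls)
            table = compute_probability_table(matrix)
            weights = weight_vector(scheme, table)
            site_data = prepare_site_data(scores, cls_index, variants, binning, table)
            n_sites = sum(len(sd.pos) for sd in site_data.values())
            n_inform = sum(int((sd.site_score > 0).sum()) for sd in site_data.values())
            lam = n_inform / n_sites if n_sites else 0.0

            regions = enumerate_windows(
                cls_genes, genome, self.window_size, self.step, self.mode,
                min_window_size=DEFAULT_MIN_WINDOW if self.mode == "windowed" else 1,
            )
            tally_regions(regions, site_data)
            for r in regions:
                r.raw_oe = weighted_oe(r.o_raw, r.e_raw, weights)
            adjust_single_exon_genes(regions, self.single_exon_delta)
            cfg = WindowFilterConfig(
                min_informative=self.min_informative,
                min_coverage_fraction=self.min_coverage_fraction,
                min_window_size=self.window_size,
                informative_rate=lam,
            )
            retained = filter_windows(regions, cfg)
            if len(retained) >= 2:
                normalize_scores(retained)
            self.tables_[cls] = table
            self.weights_[cls] = weights
            self.regions_[cls] = retained
            self.index_[cls] = RegionIndex(retained)
            self.lambda_[cls] = lam
        if not self.tables_:
            raise ValueError("no modelable chromosome class in input")
        return self

    # -- scoring ----------------------------------------------------------

    def score_position(self, chrom: str, pos: int) -> float:
        """Constraint score covering a position (max over overlapping regions)."""
        for index in self.index_.values():
            s = index.score_position(chrom, pos)
            if not np.isnan(s):
                return s
        return float("nan")

    def region_id_at(self, chrom: str, pos: int) -> str | None:
        for index in self.index_.values():
            rid = index.region_id_at(chrom, pos)
            if rid is not None:
                return rid
        return None

    def score_positions(self, chroms, positions) -> np.ndarray:
        return np.array(
            [self.score_position(c, int(p)) for c, p in zip(chroms, positions)]
        )

    def all_regions(self) -> list[ConstraintRegion]:
        return [r for rs in self.regions_.values() for r in rs]

    def to_frame(self) -> pd.DataFrame:
        return regions_to_frame(self.all_regions())
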