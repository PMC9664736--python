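"""Input parsing, validation, and normalization.

All readers convert to the package's internal 0-based half-open coordinates:
VCF, GTF and the per-position TSVs (coverage, site scores, truth sets) are
1-based on disk; BED is already 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import GeneModel, GenomeConfig, REF_ALLELES, merge_intervals
from .substitution import SiteScoreTable

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.95
DEFAULT_COVERAGE_FRACTION = 0.5   # pass = >=10X in >=50% of samples

FILTER_CRITERIA = (
    "snv",
    "pass_filter",
    "allele_count",
    "coverage",
    "reference_match",
    "in_gene",
    "has_score",
    "masked",
    "in_truth_set",
)


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise ValueError(f"malformed GTF line {lineno} in {path}")


def load_gene_models(
    gtf_path: str | Path,
    genome: GenomeConfig,
    gene_types: tuple[str, ...] = ("protein_coding",),
) -> list[GeneModel]:
    """Protein-coding gene models from a GTF: strand-separated transcript unions.

    Per gene, all transcript spans are unioned (per strand) into the merged
    interval set; exon and CDS interval lists are unioned likewise. Genes are
    returned ordered by (chromosome, start). A gene whose features span two
    chromosomes or strands is rejected.
    """
    import gffutils

    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gtype = (g.attributes.get("gene_type") or g.attributes.get("gene_biotype") or [""])[0]
        if gtype not in gene_types:
            continue
        gid = g.attributes["gene_id"][0]
        spans, exons, cds = [], [], []
        for t in db.children(g, featuretype="transcript"):
            if t.seqid != g.seqid or t.strand != g.strand:
                raise ValueError(f"gene {gid} has transcripts on another chromosome/strand")
            spans.append((t.start - 1, t.end))
        for x in db.children(g, featuretype="exon"):
            if x.seqid != g.seqid:
                raise ValueError(f"gene {gid} spans two chromosomes")
            exons.append((x.start - 1, x.end))
        for x in db.children(g, featuretype="CDS"):
            cds.append((x.start - 1, x.end))
        if not spans:
            spans = [(g.start - 1, g.end)]
        if not exons:
            exons = list(spans)
        genes.append(
            GeneModel(
                gene_id=gid, chrom=g.seqid, strand=g.strand,
                merged_intervals=spans, exons=exons, cds=cds,
            )
        )
    # Y (and anything without a model class) is dropped on load.
    genes = [g for g in genes if genome.chromosome_class(g.chrom) is not None]
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


def write_gene_models_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GENCODE-style GTF (one transcript/gene)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            s, e = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_type "protein_coding";'
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_type "protein_coding";'
            fh.write(f"{g.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            fh.write(f"{g.chrom}\tsim\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n")
            for xs, xe in g.exons:
                fh.write(f"{g.chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{tattrs}\n")
            for cs, ce in g.cds:
                fh.write(f"{g.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t{tattrs}\n")


# ---------------------------------------------------------------------------
# Exclusion mask (BED with identity fraction)
# ---------------------------------------------------------------------------

@dataclass
class ExclusionMask:
    """Merged repeat intervals with identity >= the recorded threshold."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self) -> None:
        self.intervals = {c: merge_intervals(iv) for c, iv in self.intervals.items()}
        self._starts = {c: np.array([s for s, _ in iv]) for c, iv in self.intervals.items()}
        self._ends = {c: np.array([e for _, e in iv]) for c, iv in self.intervals.items()}

    def covers(self, chrom: str, pos) -> np.ndarray:
        """Boolean array: is each position inside a masked interval."""
        p = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(len(p), dtype=bool)
        i = np.searchsorted(starts, p, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(p), dtype=bool)
        out[ok] = p[ok] < self._ends[chrom][i[ok]]
        return out

    @property
    def n_intervals(self) -> int:
        return sum(len(iv) for iv in self.intervals.values())


def load_exclusion_mask(
    bed_paths,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> ExclusionMask:
    """Merge BED records (4th column: identity fraction) at/above the threshold."""
    if isinstance(bed_paths, (str, Path)):
        bed_paths = [bed_paths]
    intervals: dict[str, list[tuple[int, int]]] = {}
    for path in bed_paths:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "identity"],
            dtype={"chrom": str},
        )
        if df["identity"].isna().any():
            raise ValueError(f"missing identity column in {path}")
        keep = df[df["identity"] >= identity_threshold]
        for row in keep.itertuples(index=False):
            intervals.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    return ExclusionMask(intervals=intervals, identity_threshold=identity_threshold)


def write_exclusion_bed(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Coverage summary
# ---------------------------------------------------------------------------

@dataclass
class CoverageTable:
    """Per-position fraction of samples at >=10X; pass = fraction >= 0.5.

    Positions absent from the table are treated as covered: the criterion
    only applies where a summary exists.
    """

    frames: dict[str, pd.Series]  # chrom -> Series(pos -> fraction), pos 0-based
    pass_fraction: float = DEFAULT_COVERAGE_FRACTION

    def passes(self, chrom: str, pos) -> np.ndarray:
        p = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        series = self.frames.get(chrom)
        if series is None:
            return np.ones(len(p), dtype=bool)
        frac = series.reindex(p).to_numpy()
        return ~(frac < self.pass_fraction)  # NaN (absent) passes


def load_coverage(path: str | Path, pass_fraction: float = DEFAULT_COVERAGE_FRACTION) -> CoverageTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "fraction_10x"}.issubset(df.columns):
        raise ValueError("coverage TSV needs columns chrom, pos, fraction_10x")
    frames = {
        str(chrom): pd.Series(
            sub["fraction_10x"].to_numpy(), index=sub["pos"].to_numpy(dtype=np.int64) - 1
        )
        for chrom, sub in df.groupby("chrom")
    }
    return CoverageTable(frames=frames, pass_fraction=pass_fraction)


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site scores (TSV: one record per ref->alt)
# ---------------------------------------------------------------------------

def load_site_scores(path: str | Path) -> SiteScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = {"chrom", "pos", "ref", "alt", "ag", "al", "dg", "dl"}
    if not req.issubset(df.columns):
        raise ValueError(f"site-score TSV needs columns {sorted(req)}")
    df = df.assign(pos=df["pos"].astype(np.int64) - 1)
    return SiteScoreTable.from_records(df)


def write_site_scores(df: pd.DataFrame, path: str | Path) -> None:
    """Write a 0-based score-record frame as a 1-based TSV."""
    out = df.assign(pos=df["pos"].astype(np.int64) + 1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Population variants (VCF)
# ---------------------------------------------------------------------------

def load_population_vcf(path: str | Path, genome: GenomeConfig | None = None) -> pd.DataFrame:
    """Read a population VCF into a biallelic SNV-candidate frame.

    Multi-allelic records are decomposed into one row per alternate allele
    with its own AC (Number=A). Y-chromosome records (no model class) are
    dropped when a genome config is supplied. Positions become 0-based.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if genome is not None and genome.chromosome_class(rec.chrom) is None:
                continue
            filters = list(rec.filter.keys())
            passing = "PASS" in filters if filters else False
            acs = rec.info.get("AC", (0,) * len(rec.alts or ()))
            if not isinstance(acs, tuple):
                acs = (acs,)
            for alt, ac in zip(rec.alts or (), acs):
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos - 1,
                        "ref": rec.ref,
                        "alt": alt,
                        "ac": int(ac),
                        "filter": "PASS" if passing else (filters[0] if filters else "."),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "filter"])


def write_population_vcf(
    df: pd.DataFrame,
    genome: GenomeConfig,
    path: str | Path,
    info_fields: dict[str, tuple[str, str, str]] | None = None,
) -> None:
    """Write a variant frame (0-based pos) as VCF with AC and optional INFO tags.

    ``info_fields`` maps column name -> (Number, Type, Description).
    """
    header = pysam.VariantHeader()
    for chrom, length in genome.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.filters.add("LowQual", None, None, "Failed quality filtering")
    header.info.add("AC", "A", "Integer", "Allele count")
    for name, (number, vtype, desc) in (info_fields or {}).items():
        header.info.add(name, number, vtype, desc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.sort_values(["chrom", "pos", "alt"]).itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos),
                stop=int(row.pos) + len(row.ref),
                alleles=(row.ref, row.alt),
            )
            rec.info["AC"] = (int(getattr(row, "ac", 1)),)
            filt = getattr(row, "filter", "PASS")
            rec.filter.add("PASS" if filt == "PASS" else "LowQual")
            for name in (info_fields or {}):
                val = getattr(row, name, None)
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    rec.info[name] = val
            out.write(rec)


# ---------------------------------------------------------------------------
# Truth sets
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "label",
    "spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl", "squirls_max",
]


def load_truth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth TSV missing columns {sorted(missing)}")
    bad = set(df["label"].unique()) - {"pathogenic", "benign"}
    if bad:
        raise ValueError(f"unknown truth labels {sorted(bad)}")
    return df.assign(pos=df["pos"].astype(np.int64) - 1)


def write_truth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.assign(pos=df["pos"].astype(np.int64) + 1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# The population-variant filter
# ---------------------------------------------------------------------------

def _gene_interval_arrays(genes: list[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by.setdefault(g.chrom, []).extend(g.merged_intervals)
    out = {}
    for chrom, ivals in by.items():
        merged = merge_intervals(ivals)
        out[chrom] = (np.array([s for s, _ in merged]), np.array([e for _, e in merged]))
    return out


def _in_intervals(arrays, chrom: str, pos: np.ndarray) -> np.ndarray:
    entry = arrays.get(chrom)
    if entry is None:
        return np.zeros(len(pos), dtype=bool)
    starts, ends = entry
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[i[ok]]
    return out


def filter_population_variants(
    variants: pd.DataFrame,
    genes: list[GeneModel],
    scores: SiteScoreTable,
    mask: ExclusionMask | None = None,
    coverage: CoverageTable | None = None,
    truth: pd.DataFrame | None = None,
    reference=None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the population-variant retention criteria; order-independent.

    A variant is retained iff it is a biallelic SNV with PASS filter and
    AC >= 1, covered (>=10X in >=50% of samples where a summary exists), its
    ref matches the reference sequence (when one is provided; the score
    track's recorded ref is checked regardless), lies in a merged
    protein-coding interval, has a score record for its specific alt, is not
    in the exclusion mask, and is absent from the truth set. Returns the
    retained frame (with a ``genes`` annotation of overlapping gene ids) and a
    per-criterion discard tally (a variant may count under several criteria).
    """
    df = variants.reset_index(drop=True).copy()
    n = len(df)
    ok = {c: np.ones(n, dtype=bool) for c in FILTER_CRITERIA}

    bases = set(REF_ALLELES)
    ok["snv"] = (
        df["ref"].astype(str).isin(bases) & df["alt"].astype(str).isin(bases)
        & (df["ref"] != df["alt"])
    ).to_numpy()
    ok["pass_filter"] = (df.get("filter", pd.Series(["PASS"] * n)) == "PASS").to_numpy()
    ok["allele_count"] = (df.get("ac", pd.Series([1] * n)).to_numpy() >= 1)

    gene_arrays = _gene_interval_arrays(genes)
    for chrom, sub in df.groupby("chrom"):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if coverage is not None:
            ok["coverage"][idx] = coverage.passes(chrom, pos)
        if mask is not None:
            ok["masked"][idx] = ~mask.covers(chrom, pos)
        ok["in_gene"][idx] = _in_intervals(gene_arrays, chrom, pos)
        # score record + recorded-ref consistency for the variant's alt
        has = np.zeros(len(idx), dtype=bool)
        if scores.has_chrom(chrom):
            cs = scores.chrom(chrom)
            rows = cs.locate(pos)
            found = rows >= 0
            refs = sub["ref"].map({b: i for i, b in enumerate(REF_ALLELES)}).to_numpy()
            alts = sub["alt"].map({b: i for i, b in enumerate(REF_ALLELES)}).to_numpy()
            safe = np.clip(rows, 0, None)
            ref_match = cs.ref_idx[safe] == refs
            alt_hit = (cs.alt_idx[safe] == alts[:, None]).any(axis=1)
            has = found & ref_match & alt_hit
        ok["has_score"][idx] = has
        if reference is not None:
            seq = reference[chrom] if not hasattr(reference, "fetch") else None
            for j, p, r in zip(idx, pos, sub["ref"]):
                base = (
                    str(seq[p]) if seq is not None
                    else reference.fetch(chrom, int(p), int(p) + 1)
                ).upper()
                ok["reference_match"][j] = base == r

    if truth is not None and len(truth):
        key = ["chrom", "pos", "ref", "alt"]
        merged = df[key].merge(truth[key].drop_duplicates(), on=key, how="left", indicator=True)
        ok["in_truth_set"] = (merged["_merge"] == "left_only").to_numpy()

    tally = {c: int((~m).sum()) for c, m in ok.items()}
    keep = np.logical_and.reduce(list(ok.values()))
    retained = df[keep].copy()

    gene_lists = []
    for row in retained.itertuples(index=False):
        hits = [g.gene_id for g in genes if g.chrom == row.chrom and g.contains(row.pos)]
        gene_lists.append(",".join(hits))
    retained["genes"] = gene_lists
    return retained.reset_index(drop=True), tally


# ---------------------------------------------------------------------------
# Model-site selection
# ---------------------------------------------------------------------------

def select_model_sites(
    scores: SiteScoreTable,
    genes: list[GeneModel],
    genome: GenomeConfig,
    mask: ExclusionMask | None = None,
    coverage: CoverageTable | None = None,
) -> dict[str, np.ndarray]:
    """Rows of the score table inside merged protein-coding sequence.

    Masked positions, coverage-failing positions, PAR positions on X, and
    chromosomes without a model class are excluded; the result feeds both the
    substitution matrix and the region tallies so sites and variants obey the
    same inclusion rules.
    """
    arrays = _gene_interval_arrays(genes)
    out: dict[str, np.ndarray] = {}
    for chrom in scores.chroms:
        if genome.chromosome_class(chrom) is None:
            continue
        cs = scores.chrom(chrom)
        keep = _in_intervals(arrays, chrom, cs.pos)
        if mask is not None:
            keep &= ~mask.covers(chrom, cs.pos)
        if coverage is not None:
            keep &= coverage.passes(chrom, cs.pos)
        for ps, pe in genome.pars_for(chrom):
            keep &= ~((cs.pos >= ps) & (cs.pos < pe))
        idx = np.nonzero(keep)[0]
        if len(idx):
            out[chrom] = idx
    return out
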