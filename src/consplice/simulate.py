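"""Desk-scale synthetic data with the statistical structure the constraint
model assumes.

A small genome of multi-exon genes on both strands is generated with a splice
score track that peaks at exon junctions (canonical sites highest, the
8-intronic/3-exonic splice region next) and a background mixture spanning all
eight score bins. Population variants arise per site with a per-reference
baseline rate; at high-score sites inside "constrained" genes the rate is
multiplied by a depletion factor d (d = 1 means no constraint, d = 0.1 means
ten-fold depletion of splice-relevant variation — the purifying-selection
premise of the constraint model). Truth variants are planted at high-score
constrained loci (pathogenic) and tolerant/low-score loci (benign), and are
excluded from the population callset to avoid leakage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .genome import GeneModel, GenomeConfig, REF_ALLELES, annotate_relative_position
from .substitution import SCORE_MAX, SiteScoreTable

# Background max-sum score mixture over the default bin edges: enough mass
# above the motif threshold that 50 bp windows carry a detectable depletion
# signal, while still concentrating most sites at low scores.
_BG_EDGES = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 4.0)
_BG_PROBS = (0.38, 0.12, 0.10, 0.08, 0.09, 0.08, 0.09, 0.06)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic bundle."""

    seed: int = 0
    n_genes: int = 40
    n_genes_x: int = 0
    constrained_fraction: float = 0.2
    exons_per_gene: int = 4
    exon_length: int = 120
    intron_length: int = 300
    intergenic_length: int = 200
    #: per-reference baseline per-site variant probability (gnomAD-like genic density)
    mu: tuple[float, float, float, float] = (0.13, 0.17, 0.17, 0.13)  # A, C, G, T
    #: depletion factor d applied at high-score sites of constrained genes
    depletion: float = 0.1
    #: summed-score threshold above which a site is treated as splice-relevant
    motif_threshold: float = 0.5
    zero_score_fraction: float = 0.15
    unscored_fraction: float = 0.01
    low_coverage_fraction: float = 0.005
    fail_filter_fraction: float = 0.01
    n_pathogenic: int = 60
    n_benign: int = 240
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not (0.0 < self.depletion <= 1.0):
            raise ValueError("depletion must be in (0, 1]")
        if not (0.0 <= self.constrained_fraction <= 1.0):
            raise ValueError("constrained_fraction must be in [0, 1]")
        if any(not (0.0 < m < 1.0) for m in self.mu):
            raise ValueError("baseline rates must be in (0, 1)")


@dataclass
class SyntheticBundle:
    """In-memory simulated inputs plus writers for the on-disk fixture forms."""

    config: SimulationConfig
    genome: GenomeConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    score_records: pd.DataFrame          # 0-based, one row per ref->alt
    scores: SiteScoreTable
    variants: pd.DataFrame               # population callset (0-based)
    coverage_records: pd.DataFrame       # 1-based TSV form
    mask_records: pd.DataFrame           # BED form with identity column
    truth: pd.DataFrame                  # 0-based with labels and annotations
    constrained_genes: frozenset[str]

    def write(self, outdir: str | Path) -> None:
        """Write FASTA/GTF/TSV/VCF/BED fixtures plus a manifest; deterministic."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "reference.fa", "w") as fh:
            for chrom in sorted(self.reference):
                fh.write(f">{chrom}\n")
                seq = self.reference[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        cio.write_gene_models_gtf(self.genes, out / "genes.gtf")
        cio.write_site_scores(self.score_records, out / "site_scores.tsv")
        cio.write_population_vcf(self.variants, self.genome, out / "population.vcf")
        cio.write_coverage(self.coverage_records, out / "coverage.tsv")
        cio.write_exclusion_bed(self.mask_records, out / "mask.bed")
        cio.write_truth_tsv(self.truth, out / "truth.tsv")
        manifest = {
            "config": dataclasses.asdict(self.config),
            "genome": {
                "chrom_lengths": self.genome.chrom_lengths,
                "par_intervals": [list(p) for p in self.genome.par_intervals],
                "build": self.genome.build,
            },
            "constrained_genes": sorted(self.constrained_genes),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _split_into_deltas(rng: np.random.Generator, sums: np.ndarray) -> np.ndarray:
    """Split summed scores into four delta components, each in [0, 1]."""
    parts = rng.dirichlet(np.ones(4), size=len(sums)) * sums[:, None]
    for _ in range(4):  # redistribute any component above 1
        excess = np.clip(parts - 1.0, 0.0, None)
        if not excess.any():
            break
        parts = np.minimum(parts, 1.0)
        room = np.clip(1.0 - parts, 0.0, None)
        total_room = room.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            parts = parts + np.where(total_room > 0, room / total_room, 0) * excess.sum(
                axis=1, keepdims=True
            )
    return np.clip(parts, 0.0, 1.0)


def _gene_layout(cfg: SimulationConfig, rng: np.random.Generator, chrom: str, n: int):
    """Place n genes with alternating strands; return GeneModels and chrom length."""
    genes = []
    cursor = cfg.intergenic_length
    for i in range(n):
        exon_lens = rng.integers(cfg.exon_length - 20, cfg.exon_length + 21, cfg.exons_per_gene)
        intron_lens = rng.integers(cfg.intron_length - 50, cfg.intron_length + 51, max(cfg.exons_per_gene - 1, 0))
        exons = []
        p = cursor
        for k, el in enumerate(exon_lens):
            exons.append((p, p + int(el)))
            p += int(el)
            if k < len(intron_lens):
                p += int(intron_lens[k])
        gid = f"{'GX' if chrom != 'chr1' else 'G'}{i:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                merged_intervals=[(exons[0][0], exons[-1][1])],
                exons=exons,
            )
        )
        cursor = p + cfg.intergenic_length
    return genes, cursor + cfg.intergenic_length


def _site_classes(gene: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the merged span and their class: 2=canonical, 1=splice region, 0=background."""
    s, e = gene.span
    pos = np.arange(s, e)
    cls = np.zeros(len(pos), dtype=np.int8)
    n = len(gene.exons)
    for k, (xs, xe) in enumerate(gene.exons):
        # exonic splice-region bases at internal junctions
        if k > 0:
            left = np.arange(xs, min(xs + 3, xe)) - s
            cls[left] = np.maximum(cls[left], 1)
        if k < n - 1:
            right = np.arange(max(xe - 3, xs), xe) - s
            cls[right] = np.maximum(cls[right], 1)
    for k in range(n - 1):  # introns
        istart, iend = gene.exons[k][1], gene.exons[k + 1][0]
        left8 = np.arange(istart, min(istart + 8, iend)) - s
        right8 = np.arange(max(iend - 8, istart), iend) - s
        cls[left8] = np.maximum(cls[left8], 1)
        cls[right8] = np.maximum(cls[right8], 1)
        left2 = np.arange(istart, min(istart + 2, iend)) - s
        right2 = np.arange(max(iend - 2, istart), iend) - s
        cls[left2] = 2
        cls[right2] = 2
    return pos, cls


def _draw_background_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    bins = rng.choice(len(_BG_PROBS), size=n, p=_BG_PROBS)
    lo = np.asarray(_BG_EDGES[:-1])[bins]
    hi = np.asarray(_BG_EDGES[1:])[bins]
    return rng.uniform(lo, hi)


def simulate_bundle(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate the full synthetic input bundle; reproducible under the seed."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    genes_a, len_a = _gene_layout(cfg, rng, cfg.chrom, cfg.n_genes)
    genes: list[GeneModel] = list(genes_a)
    chrom_lengths = {cfg.chrom: int(len_a)}
    par_intervals: tuple = ()
    if cfg.n_genes_x > 0:
        genes_x, len_x = _gene_layout(cfg, rng, "chrX", cfg.n_genes_x)
        genes.extend(genes_x)
        chrom_lengths["chrX"] = int(len_x)
        # PAR over the first 100 bp of the first X gene: its windows are dropped
        gx = genes_x[0]
        par_intervals = (("chrX", gx.span[0], min(gx.span[0] + 100, gx.span[1])),)
    genome = GenomeConfig(
        chrom_lengths=chrom_lengths, par_intervals=par_intervals, build="synthetic"
    )

    reference = {
        chrom: "".join(rng.choice(list(REF_ALLELES), size=length))
        for chrom, length in sorted(chrom_lengths.items())
    }

    n_constrained = int(round(cfg.constrained_fraction * len(genes)))
    constrained = frozenset(
        rng.choice([g.gene_id for g in genes], size=n_constrained, replace=False).tolist()
    )

    # --- score track -------------------------------------------------------
    rec_frames = []
    site_meta = []  # (chrom, pos, gene_id, max_sum) for variant generation
    for gene in genes:
        pos, cls = _site_classes(gene)
        n = len(pos)
        max_sum = np.empty(n)
        bg = cls == 0
        max_sum[bg] = _draw_background_scores(rng, int(bg.sum()))
        near = cls == 1
        max_sum[near] = rng.uniform(0.8, 2.5, int(near.sum()))
        canon = cls == 2
        max_sum[canon] = rng.uniform(2.5, SCORE_MAX, int(canon.sum()))
        # a fraction of background sites carry no splicing signal at all
        zero = bg & (rng.random(n) < cfg.zero_score_fraction)
        max_sum[zero] = 0.0
        unscored = rng.random(n) < cfg.unscored_fraction

        seq = reference[gene.chrom]
        refs = np.array([seq[p] for p in pos])
        keep = ~unscored
        kpos, krefs, ksums = pos[keep], refs[keep], max_sum[keep]
        m = len(kpos)
        # three alternates per site; one random slot carries the max sum
        alt_choices = np.array([[b for b in REF_ALLELES if b != r] for r in krefs])
        slot_max = rng.integers(0, 3, m)
        ratios = rng.uniform(0.15, 1.0, (m, 3))
        ratios[np.arange(m), slot_max] = 1.0
        sums3 = ksums[:, None] * ratios
        for a in range(3):
            deltas = _split_into_deltas(rng, sums3[:, a])
            rec_frames.append(
                pd.DataFrame(
                    {
                        "chrom": gene.chrom,
                        "pos": kpos,
                        "ref": krefs,
                        "alt": alt_choices[:, a],
                        "ag": deltas[:, 0],
                        "al": deltas[:, 1],
                        "dg": deltas[:, 2],
                        "dl": deltas[:, 3],
                    }
                )
            )
        site_meta.append(
            pd.DataFrame(
                {
                    "chrom": gene.chrom,
                    "pos": kpos,
                    "ref": krefs,
                    "gene_id": gene.gene_id,
                    "max_sum": ksums,
                    "constrained": gene.gene_id in constrained,
                }
            )
        )
    score_records = (
        pd.concat(rec_frames, ignore_index=True)
        .sort_values(["chrom", "pos", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )
    sites = pd.concat(site_meta, ignore_index=True)
    scores = SiteScoreTable.from_records(score_records)

    # --- population variants ------------------------------------------------
    mu = dict(zip(REF_ALLELES, cfg.mu))
    rate = sites["ref"].map(mu).to_numpy()
    depleted = sites["constrained"].to_numpy() & (sites["max_sum"].to_numpy() >= cfg.motif_threshold)
    rate = np.where(depleted, rate * cfg.depletion, rate)
    has_var = rng.random(len(sites)) < rate
    vsites = sites[has_var].reset_index(drop=True)
    alt_slot = rng.integers(0, 3, len(vsites))
    alt_base = np.array(
        [
            [b for b in REF_ALLELES if b != r][k]
            for r, k in zip(vsites["ref"], alt_slot)
        ]
    )
    variants = pd.DataFrame(
        {
            "chrom": vsites["chrom"],
            "pos": vsites["pos"],
            "ref": vsites["ref"],
            "alt": alt_base,
            "ac": 1 + rng.geometric(0.4, len(vsites)),
            "filter": np.where(
                rng.random(len(vsites)) < cfg.fail_filter_fraction, "LowQual", "PASS"
            ),
        }
    )

    # --- coverage and mask ---------------------------------------------------
    cov_frac = rng.uniform(0.7, 1.0, len(sites))
    lowcov = rng.random(len(sites)) < cfg.low_coverage_fraction
    cov_frac[lowcov] = rng.uniform(0.0, 0.45, int(lowcov.sum()))
    coverage_records = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"].to_numpy() + 1,
            "fraction_10x": np.round(cov_frac, 4),
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    tolerant_genes = [g for g in genes_a if g.gene_id not in constrained]
    mask_rows = []
    if tolerant_genes:
        g0 = tolerant_genes[0]
        mask_rows.append((g0.chrom, g0.span[0] + 10, g0.span[0] + 110, 0.97))
        mask_rows.append((g0.chrom, g0.span[0] + 200, g0.span[0] + 260, 0.80))
    mask_records = pd.DataFrame(mask_rows, columns=["chrom", "start", "end", "identity"])

    # --- truth set -----------------------------------------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    autosomal = sites["chrom"] == cfg.chrom
    path_pool = sites[
        autosomal & sites["constrained"] & (sites["max_sum"] >= cfg.motif_threshold)
    ]
    benign_pool = sites[autosomal & ~sites["constrained"]]
    n_path = min(cfg.n_pathogenic, len(path_pool))
    n_ben = min(cfg.n_benign, len(benign_pool))
    path_rows = path_pool.iloc[
        rng.choice(len(path_pool), size=n_path, replace=False)
    ]
    benign_rows = benign_pool.iloc[
        rng.choice(len(benign_pool), size=n_ben, replace=False)
    ]

    record_index = score_records.set_index(["chrom", "pos", "alt"]).sort_index()

    def _truth_frame(rows: pd.DataFrame, label: str, squirls_mean: float) -> pd.DataFrame:
        recs = []
        for row in rows.itertuples(index=False):
            cs = scores.chrom(row.chrom)
            i = int(cs.locate(row.pos)[0])
            slot = int(np.nanargmax(cs.sums[i]))
            alt = REF_ALLELES[cs.alt_idx[i, slot]]
            rec = record_index.loc[(row.chrom, row.pos, alt)]
            recs.append(
                {
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "ref": row.ref,
                    "alt": alt,
                    "label": label,
                    "spliceai_ag": rec["ag"],
                    "spliceai_al": rec["al"],
                    "spliceai_dg": rec["dg"],
                    "spliceai_dl": rec["dl"],
                    "squirls_max": float(
                        np.clip(rng.normal(squirls_mean, 0.15), 0.0, 1.0)
                    ),
                    "position_label": annotate_relative_position(
                        int(row.pos), gene_by_id[row.gene_id]
                    ),
                    "true_class": "constrained" if row.constrained else "tolerant",
                }
            )
        return pd.DataFrame(recs)

    truth = pd.concat(
        [
            _truth_frame(path_rows, "pathogenic", 0.75),
            _truth_frame(benign_rows, "benign", 0.25),
        ],
        ignore_index=True,
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    # leakage control: truth variants never appear in the population callset
    key = ["chrom", "pos", "ref", "alt"]
    merged = variants.merge(truth[key].drop_duplicates(), on=key, how="left", indicator=True)
    variants = (
        variants[(merged["_merge"] == "left_only").to_numpy()]
        .sort_values(["chrom", "pos", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )

    return SyntheticBundle(
        config=cfg,
        genome=genome,
        reference=reference,
        genes=genes,
        score_records=score_records,
        scores=scores,
        variants=variants,
        coverage_records=coverage_records,
        mask_records=mask_records,
        truth=truth,
        constrained_genes=constrained,
    )


def ground_truth_labels(bundle: SyntheticBundle, regions=None) -> pd.DataFrame:
    """Planted constrained/tolerant class for each region a model would score.

    ``regions`` defaults to the standard 50 bp tiling of the bundle's genes;
    a region is constrained iff its gene carries the planted depletion.
    """
    from .constraint import enumerate_windows

    if regions is None:
        regions = enumerate_windows(bundle.genes, bundle.genome)
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "constrained": [
                any(g in bundle.constrained_genes for g in r.gene_ids) for r in regions
            ],
        }
    )
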