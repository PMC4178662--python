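"""Synthetic data with known truth for every pipeline stage.

Generates genomes with multi-exon gene models, UTRs, intergenic spacers and
CNS intervals; a diploid population genotype table whose per-class
polymorphism is drawn from Poisson-random-field expectations under
class-specific gamma DFEs; a three-way outgroup alignment with
lineage-specific substitutions (a known fraction adaptive); localized
diversity troughs around recent adaptive fixations; IBD tracts; realistic
QUAL/Dels/DP/PL noise exercising every genotype filter; and a log-normal
expression table coupled to per-gene selection strength.

Genotypes are drawn site-independently (no linkage) apart from the injected
troughs and IBD tracts: no downstream statistic here needs haplotype LD,
and independence keeps the generator analytically checkable.  Ancestral
states are exact by construction (the outgroups carry the ancestral base),
so unfolded spectra polarize perfectly unless the polarization-error knob
is turned on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .afs import AFS
from .annotate import ClassMap, CnsCategory, SiteClass, classify_sites
from .dfe import SfsEngine, omega_nonadaptive
from .divergence import MISSING, TripletAlignment
from .filters import IBDTract
from .genome import CnsInterval, Feature, GenomeBundle
from .variants import VariantTable

__all__ = ["GammaDFE", "NEUTRAL", "SimConfig", "SimTruth",
           "SimulatedDataset", "simulate_genome", "sample_sfs_prf",
           "simulate_population", "simulate_divergence_triplet",
           "inject_sweep_troughs", "simulate_expression",
           "simulate_dataset", "default_scenario", "sweep_scenario"]

_SENSE_CODONS = None


@dataclass(frozen=True)
class GammaDFE:
    """Gamma DFE over the deleterious strength |S| = 4*Ne*s.

    shape == mean == 0 denotes strict neutrality (point mass at S = 0).
    """
    shape: float = 0.0
    mean: float = 0.0

    def __post_init__(self):
        if self.mean < 0:
            raise ValueError("E[S] must be >= 0 for a deleterious DFE")
        if self.mean > 0 and self.shape <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def neutral(self) -> bool:
        return self.mean == 0.0

    def omega_na(self) -> float:
        return 1.0 if self.neutral else omega_nonadaptive(self.shape,
                                                          self.mean)

    def scaled(self, factor: float) -> "GammaDFE":
        return self if self.neutral else GammaDFE(self.shape,
                                                  self.mean * factor)


NEUTRAL = GammaDFE()

# class-wise defaults: gamma parameters chosen so the per-class selection
# structure matches a strongly outcrossing crucifer: strong purifying
# selection at replacement sites (~14% effectively neutral), intermediate
# at UTRs (~45% neutral) and CNSs (~28% neutral), weak at intron junctions
# (~68% neutral), effectively neutral elsewhere.
DEFAULT_CLASS_DFES: dict[str, GammaDFE] = {
    SiteClass.zero_fold.name: GammaDFE(0.3, 302.0),
    SiteClass.four_fold.name: NEUTRAL,
    SiteClass.utr5.name: GammaDFE(0.3, 5.9),
    SiteClass.utr3.name: GammaDFE(0.3, 5.9),
    SiteClass.intron_internal.name: NEUTRAL,
    SiteClass.intron_junction.name: GammaDFE(0.3, 1.3),
    SiteClass.intergenic.name: NEUTRAL,
    CnsCategory.intergenic_cns.name: GammaDFE(0.3, 29.7),
    CnsCategory.intronic_cns.name: GammaDFE(0.3, 12.0),
    CnsCategory.utr5_cns.name: GammaDFE(0.3, 29.7),
    CnsCategory.utr3_cns.name: GammaDFE(0.3, 29.7),
    CnsCategory.snc_cns.name: GammaDFE(0.3, 80.0),
}

DEFAULT_ALPHA: dict[str, float] = {
    SiteClass.zero_fold.name: 0.417,
    SiteClass.utr5.name: 0.35,
    SiteClass.utr3.name: 0.35,
    SiteClass.intron_junction.name: 0.2,
    CnsCategory.intergenic_cns.name: 0.35,
    CnsCategory.intronic_cns.name: 0.35,
    CnsCategory.utr5_cns.name: 0.35,
    CnsCategory.utr3_cns.name: 0.35,
    CnsCategory.snc_cns.name: 0.35,
}


@dataclass
class SimConfig:
    # genome structure
    n_contigs: int = 2
    contig_length: int = 400_000
    utr5_len: int = 150
    utr3_len: int = 200
    n_exons: int = 3
    exon_cds_len: int = 300
    intron_len: int = 120
    spacer: int = 1500
    cns_intergenic_len: int = 60
    cns_intron_len: int = 30
    cns_utr_len: int = 25
    cns_snc_len: int = 40
    cns_density: float = 1.0      # scale factor on CNS placement
    # population model
    n_individuals: int = 13
    theta: float = 0.022          # neutral 4*Ne*mu per site
    class_dfes: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_DFES))
    alpha: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    d_s: float = 0.14             # lineage-specific neutral divergence
    outgroup_disagreement: float = 0.05
    gap_fraction: float = 0.01
    gap_mean_len: int = 150
    polarization_error: float = 0.0
    # genotype noise (chosen to exercise every filter branch)
    mean_depth: float = 34.0
    low_qual_fraction: float = 0.05
    dels_fraction: float = 0.02
    pl_fail_fraction: float = 0.03
    triallelic_fraction: float = 0.001
    bad_region_fraction: float = 0.0   # per-contig low-quality region span
    # IBD (tracts longer than the 200 kb detection window, as the large
    # biparental-inbreeding stretches they emulate)
    n_ibd_tracts: int = 2
    ibd_tract_len: int = 300_000
    # sweeps: troughs persist only around the recent fraction of adaptive
    # fixations (trough lifetime is a small slice of the divergence time);
    # the default keeps the total trough footprint (~6*decay per anchor)
    # near 10% of the genome, as in the emulated outcrosser
    trough_depth: float = 0.5
    trough_decay: float = 5000.0
    recent_fraction: float = 0.0005
    # gene-level clustering of positive selection: with fraction < 1 only
    # that share of genes is adaptive-prone (alpha below), the rest evolve
    # under purifying selection alone
    adaptive_gene_fraction: float = 1.0
    adaptive_gene_alpha: float = 0.75
    mutation_elevation: float = 1.0
    mutation_elevation_decay: float = 2000.0
    # regional diversity heterogeneity: a smooth log-normal field over the
    # chromosome (linked selection / local Ne variation) multiplying the
    # per-site polymorphism rate; mean 1 by construction
    theta_regional_sd: float = 0.4
    theta_regional_scale: int = 30_000
    # expression
    fpkm_log_mean: float = math.log(15.0)
    fpkm_log_sigma: float = 1.5
    low_expression_fraction: float = 0.30
    expression_coupling: float = 3.8

    def gene_span(self) -> int:
        return (self.utr5_len + self.n_exons * self.exon_cds_len
                + (self.n_exons - 1) * self.intron_len + self.utr3_len)


def default_scenario() -> SimConfig:
    """Whole-genome study conditions (diversity, DFE, alpha, expression)."""
    return SimConfig()


def sweep_scenario(depth: float = 0.5) -> SimConfig:
    """Study conditions for the sweep scan.

    Positive selection clusters in a 20% subset of adaptive-prone genes
    (as for defense and reproduction genes in real outcrossers), so silent
    substitutions in the purifying-only majority provide a comparison set
    whose windows are not sitting inside someone else's trough; a
    substantial recent fraction of adaptive fixations carries a trough.
    Genes are sparse (every ~14 kb) so trough footprints (~6 * decay per
    anchor) do not blanket the genome, and the genome is large enough
    (2 x 1.5 Mb) that the pooled 4-fold divergence denominator of the
    diversity/divergence ratio is well counted.
    """
    alpha = {SiteClass.zero_fold.name: 0.417,
             CnsCategory.intergenic_cns.name: 0.35,
             CnsCategory.intronic_cns.name: 0.35,
             CnsCategory.utr5_cns.name: 0.35,
             CnsCategory.utr3_cns.name: 0.35,
             CnsCategory.snc_cns.name: 0.35}
    return replace(default_scenario(),
                   contig_length=1_500_000, spacer=12_000, alpha=alpha,
                   adaptive_gene_fraction=0.2, adaptive_gene_alpha=0.75,
                   recent_fraction=0.15, trough_depth=depth,
                   n_ibd_tracts=0, low_qual_fraction=0.0,
                   dels_fraction=0.0, pl_fail_fraction=0.0,
                   triallelic_fraction=0.0, outgroup_disagreement=0.02,
                   gap_fraction=0.0)


@dataclass
class SimTruth:
    """Ground truth the estimators are judged against."""
    config: SimConfig
    seed: int
    gene_ids: list[str]
    gene_fpkm: np.ndarray
    gene_s_multiplier: np.ndarray
    ibd_tracts: list[IBDTract]
    registry: pd.DataFrame | None = None   # substitution truth
    gene_adaptive: np.ndarray | None = None  # adaptive-prone gene flags

    def gene_alpha(self, gene_idx: int) -> float:
        if self.config.adaptive_gene_fraction >= 1.0 or \
                self.gene_adaptive is None:
            return self.config.alpha.get(SiteClass.zero_fold.name, 0.0)
        return (self.config.adaptive_gene_alpha
                if self.gene_adaptive[gene_idx] else 0.0)

    def gene_dfe(self, gene_idx: int) -> GammaDFE:
        base = self.config.class_dfes[SiteClass.zero_fold.name]
        return base.scaled(float(self.gene_s_multiplier[gene_idx]))


@dataclass
class SimulatedDataset:
    bundle: GenomeBundle
    class_map: ClassMap
    truth: SimTruth
    table: VariantTable
    alignment: TripletAlignment
    expression: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return self.table.samples


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data.CodonTable import standard_dna_table
        _SENSE_CODONS = sorted(standard_dna_table.forward_table)
    return _SENSE_CODONS


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator) -> GenomeBundle:
    """Random genome with the configured gene architecture.

    Genes alternate strand; CDS sequence is drawn from sense codons (no
    internal stops); introns are long enough (default 120 bp) that the
    30 bp junction / internal split is exercised; CNS intervals land in
    intergenic, intronic and UTR sequence, plus a small-noncoding-RNA
    category in intergenic spacers.
    """
    if config.intron_len < 70:
        raise ValueError("introns must be >= 70 bp so the junction/internal "
                         "split is exercised")
    cds_len = config.n_exons * config.exon_cds_len
    if cds_len % 3 != 0:
        raise ValueError("total CDS length must be divisible by 3 for the "
                         "requested exon layout")
    codons = _sense_codons()
    sequences: dict[str, str] = {}
    features: list[Feature] = []
    cns: list[CnsInterval] = []
    gene_i = 0
    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        seq = rng.choice(list("ACGT"), size=config.contig_length)
        span = config.gene_span()

        def draw_spacer():
            # irregular intergenic spacing (a regular gene lattice would
            # create artificial periodicity in distance-anchored profiles)
            return max(300, int(rng.uniform(0.5, 1.5) * config.spacer))

        spacer = draw_spacer()
        pos = spacer
        while pos + span + 300 <= config.contig_length:
            gid = f"g{gene_i + 1:05d}"
            strand = "+" if gene_i % 2 == 0 else "-"
            cds_codons = rng.choice(codons, size=cds_len // 3)
            cds_seq = "".join(cds_codons)
            if strand == "-":
                comp = str.maketrans("ACGT", "TGCA")
                cds_seq = cds_seq.translate(comp)[::-1]
            # genomic layout (always left-to-right): utr_a, exons/introns,
            # utr_b; for '-' genes utr_a is the 3' UTR
            utr_a_len = config.utr5_len if strand == "+" else config.utr3_len
            utr_b_len = config.utr3_len if strand == "+" else config.utr5_len
            g_start = pos
            p = pos
            utr_a = (p, p + utr_a_len)
            p += utr_a_len
            cds_segs = []
            cds_cursor = 0
            for e in range(config.n_exons):
                s, epos = p, p + config.exon_cds_len
                cds_segs.append((s, epos))
                seg = cds_seq[cds_cursor:cds_cursor + config.exon_cds_len]
                seq[s:epos] = list(seg)
                cds_cursor += config.exon_cds_len
                p = epos
                if e < config.n_exons - 1:
                    p += config.intron_len
            utr_b = (p, p + utr_b_len)
            p += utr_b_len
            g_end = p
            features.append(Feature(contig, g_start, g_end, strand, "gene",
                                    gid, 0))
            ftype_a = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
            ftype_b = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
            features.append(Feature(contig, *utr_a, strand, ftype_a, gid, 0))
            features.append(Feature(contig, *utr_b, strand, ftype_b, gid, 0))
            # exons cover UTR+CDS at the gene ends
            exon_spans = []
            for k, (s, e) in enumerate(cds_segs):
                es = utr_a[0] if k == 0 else s
                ee = utr_b[1] if k == len(cds_segs) - 1 else e
                exon_spans.append((es, ee))
            if config.n_exons == 1:
                exon_spans = [(utr_a[0], utr_b[1])]
            for s, e in exon_spans:
                features.append(Feature(contig, s, e, strand, "exon", gid, 0))
            order = cds_segs if strand == "+" else cds_segs[::-1]
            cum = 0
            phases = {}
            for s, e in order:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s
            for s, e in cds_segs:
                features.append(Feature(contig, s, e, strand, "CDS", gid,
                                        phases[(s, e)]))
            # CNS placement
            if config.cns_density > 0:
                if rng.random() < config.cns_density and \
                        spacer > config.cns_intergenic_len + 220:
                    off = int(rng.integers(100, spacer
                                           - config.cns_intergenic_len - 100))
                    s0 = g_start - spacer + off
                    cns.append(CnsInterval(contig, s0,
                                           s0 + config.cns_intergenic_len,
                                           "intergenic_cns"))
                if gene_i % 3 == 0 and rng.random() < config.cns_density \
                        and spacer > config.cns_snc_len + 120:
                    off = int(rng.integers(50, spacer
                                           - config.cns_snc_len - 50))
                    s0 = g_start - spacer + off
                    cns.append(CnsInterval(contig, s0,
                                           s0 + config.cns_snc_len,
                                           "snc_cns"))
                if gene_i % 2 == 0 and config.n_exons > 1:
                    i_start = cds_segs[0][1]
                    mid = i_start + (config.intron_len
                                     - config.cns_intron_len) // 2
                    cns.append(CnsInterval(contig, mid,
                                           mid + config.cns_intron_len,
                                           "intronic_cns"))
                if gene_i % 2 == 1:
                    a_cat = "utr5_cns" if strand == "+" else "utr3_cns"
                    mid = utr_a[0] + (utr_a_len - config.cns_utr_len) // 2
                    cns.append(CnsInterval(contig, mid,
                                           mid + config.cns_utr_len, a_cat))
                    b_cat = "utr3_cns" if strand == "+" else "utr5_cns"
                    mid = utr_b[0] + (utr_b_len - config.cns_utr_len) // 2
                    cns.append(CnsInterval(contig, mid,
                                           mid + config.cns_utr_len, b_cat))
            spacer = draw_spacer()
            pos = g_end + spacer
            gene_i += 1
        sequences[contig] = "".join(seq)
    return GenomeBundle(sequences, features, cns)


# ---------------------------------------------------------------------------
# PRF spectrum sampling (AFS-level)
# ---------------------------------------------------------------------------

def sample_sfs_prf(theta: float, n_chrom: int, dfe: GammaDFE,
                   n_sites: int, rng: np.random.Generator) -> AFS:
    """Poisson draw of an AFS with class means from the PRF expectations
    under ``dfe``; the monomorphic class absorbs the remainder."""
    if n_chrom < 2:
        raise ValueError("need n_chrom >= 2")
    counts = np.zeros(n_chrom + 1)
    if n_sites == 0:
        return AFS("simulated", n_chrom, counts)
    engine = SfsEngine.get(n_chrom)
    shape = (engine.sfs([0.0])[0] if dfe.neutral
             else engine.gamma_sfs(dfe.shape, dfe.mean))
    mean = n_sites * theta * shape
    if mean.sum() > n_sites:
        raise ValueError("theta too large: expected polymorphic sites "
                         "exceed n_sites")
    counts[1:n_chrom] = rng.poisson(mean)
    counts[0] = max(n_sites - counts.sum(), 0)
    return AFS("simulated", n_chrom, counts)


# ---------------------------------------------------------------------------
# per-site selection regime lookup
# ---------------------------------------------------------------------------

def _site_regimes(bundle: GenomeBundle, class_map: ClassMap,
                  truth: SimTruth):
    """For each contig: array of bucket ids; bucket -> (GammaDFE, alpha,
    base class DFE).

    CNS categories override the primary class; 0-fold sites get the gene's
    expression-coupled DFE while their adaptive substitution rate stays
    anchored to the class-level DFE (positive selection is not coupled to
    expression).  The excluded coding class evolves like a weakly selected
    class (it is never analyzed).
    """
    from .divergence import gene_index
    cfg = truth.config
    gidx, genes = gene_index(bundle)
    buckets: list[tuple[GammaDFE, float, GammaDFE]] = []
    bucket_of: dict = {}

    def bucket(dfe: GammaDFE, alpha: float,
               base: GammaDFE | None = None) -> int:
        base = base if base is not None else dfe
        key = (dfe.shape, dfe.mean, alpha, base.shape, base.mean)
        if key not in bucket_of:
            bucket_of[key] = len(buckets)
            buckets.append((dfe, alpha, base))
        return bucket_of[key]

    zero_base = cfg.class_dfes[SiteClass.zero_fold.name]
    gene_bucket = {}
    for gi in range(len(genes)):
        gene_bucket[gi] = bucket(truth.gene_dfe(gi), truth.gene_alpha(gi),
                                 zero_base)
    out = {}
    excluded = GammaDFE(0.3, 50.0)
    for contig in bundle.sequences:
        cls = class_map.classes[contig]
        cns = class_map.cns[contig]
        gi = gidx[contig]
        ids = np.empty(cls.size, dtype=np.int32)
        for c in SiteClass:
            dfe = cfg.class_dfes.get(c.name, NEUTRAL)
            if c == SiteClass.other_coding_excluded:
                dfe = excluded
            ids[cls == c] = bucket(dfe, cfg.alpha.get(c.name, 0.0))
        for c in CnsCategory:
            if c == CnsCategory.none:
                continue
            dfe = cfg.class_dfes.get(c.name, NEUTRAL)
            ids[cns == c] = bucket(dfe, cfg.alpha.get(c.name, 0.0))
        zero = (cls == SiteClass.zero_fold) & (cns == CnsCategory.none)
        sel = zero & (gi >= 0)
        ids[sel] = np.array([gene_bucket[g] for g in gi[sel]],
                            dtype=np.int32)
        out[contig] = ids
    return out, buckets


def _bucket_rates(buckets, d_s: float):
    """Per-bucket total substitution rate and adaptive-label probability.

    Nonadaptive rate follows the bucket's own DFE through the fixation-rate
    ratio; the adaptive rate is anchored to the class base DFE and alpha,
    d_a = d_s * omega_na(base) * alpha / (1 - alpha), so gene-level DFE
    variation moves the nonadaptive rate (and hence gene-level alpha)
    without changing the adaptive substitution rate.
    """
    rate = np.empty(len(buckets))
    p_adapt = np.empty(len(buckets))
    for b, (dfe, a, base) in enumerate(buckets):
        d_na = d_s * dfe.omega_na()
        d_a = d_s * base.omega_na() * a / (1.0 - a) if a < 1 else np.nan
        rate[b] = d_na + d_a
        p_adapt[b] = d_a / rate[b] if rate[b] > 0 else 0.0
    return rate, p_adapt


# ---------------------------------------------------------------------------
# divergence triplet
# ---------------------------------------------------------------------------

def simulate_divergence_triplet(bundle: GenomeBundle, class_map: ClassMap,
                                truth: SimTruth, rng: np.random.Generator
                                ) -> tuple[TripletAlignment, pd.DataFrame]:
    """Outgroup rows plus a registry of lineage-specific substitutions.

    At a substitution the outgroups carry the (shared) ancestral base and
    the focal reference the derived one.  Per class the substitution rate
    is d_s for neutral classes and d_s * omega_na / (1 - alpha) for
    selected ones, each fixation labelled adaptive with probability alpha
    and 'recent' (trough-bearing) with the configured recent fraction.
    """
    cfg = truth.config
    regimes, buckets = _site_regimes(bundle, class_map, truth)
    rate_of, alpha_of = _bucket_rates(buckets, cfg.d_s)
    from .divergence import encode_seq
    focal, og1, og2 = {}, {}, {}
    rows = []
    for contig, seq in bundle.sequences.items():
        f = encode_seq(seq)
        o = f.copy()
        ids = regimes[contig]
        rate = rate_of[ids]
        sub = rng.random(f.size) < rate
        # substituted: outgroups carry a different (ancestral) base
        subs_pos = np.flatnonzero(sub)
        shift = rng.integers(1, 4, size=subs_pos.size)
        o[subs_pos] = (f[subs_pos] + shift) % 4
        o1 = o.copy()
        o2 = o.copy()
        # outgroup-only divergence: o2 differs, site unpolarizable
        dis = rng.random(f.size) < cfg.outgroup_disagreement
        dis &= ~sub
        dpos = np.flatnonzero(dis)
        o2[dpos] = (o2[dpos] + rng.integers(1, 4, size=dpos.size)) % 4
        # alignment gaps in the outgroups
        for row in (o1, o2):
            if cfg.gap_fraction > 0:
                n_gaps = rng.poisson(cfg.gap_fraction * f.size
                                     / cfg.gap_mean_len)
                for _ in range(n_gaps):
                    start = int(rng.integers(0, f.size))
                    length = int(rng.geometric(1.0 / cfg.gap_mean_len))
                    row[start:start + length] = MISSING
        adaptive = rng.random(subs_pos.size) < alpha_of[ids[subs_pos]]
        recent = adaptive & (rng.random(subs_pos.size)
                             < cfg.recent_fraction)
        cls = class_map.classes[contig][subs_pos]
        cns = class_map.cns[contig][subs_pos]
        rows.append(pd.DataFrame({
            "contig": contig, "pos": subs_pos,
            "site_class": [SiteClass(c).name for c in cls],
            "cns_category": [CnsCategory(c).name for c in cns],
            "adaptive": adaptive, "recent": recent}))
        focal[contig], og1[contig], og2[contig] = f, o1, o2
    registry = (pd.concat(rows, ignore_index=True) if rows
                else pd.DataFrame(columns=["contig", "pos", "site_class",
                                           "cns_category", "adaptive",
                                           "recent"]))
    return TripletAlignment(focal, og1, og2), registry


# ---------------------------------------------------------------------------
# population genotype table
# ---------------------------------------------------------------------------

def _regional_theta_field(contig_len: int, sd: float, scale: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative diversity field with E[multiplier] = 1."""
    if sd <= 0:
        return np.ones(contig_len)
    n_knots = max(2, int(np.ceil(contig_len / scale)) + 1)
    knots = rng.normal(-0.5 * sd * sd, sd, size=n_knots)
    x = np.arange(contig_len) / scale
    return np.exp(np.interp(x, np.arange(n_knots), knots))


def _elevation(contig_len: int, sub_pos: np.ndarray, factor: float,
               decay: float) -> np.ndarray:
    """Local mutation-rate multiplier around substitutions (nearest one)."""
    if factor <= 1.0 or sub_pos.size == 0:
        return np.ones(contig_len)
    pos = np.arange(contig_len)
    order = np.sort(sub_pos)
    right = np.searchsorted(order, pos)
    d_right = np.where(right < order.size,
                       np.abs(order[np.minimum(right, order.size - 1)] - pos),
                       np.inf)
    d_left = np.where(right > 0,
                      np.abs(pos - order[np.maximum(right - 1, 0)]), np.inf)
    dist = np.minimum(d_left, d_right)
    return 1.0 + (factor - 1.0) * np.exp(-dist / decay)


def simulate_population(bundle: GenomeBundle, class_map: ClassMap,
                        truth: SimTruth, registry: pd.DataFrame,
                        rng: np.random.Generator) -> VariantTable:
    """All-sites genotype table for the diploid sample.

    Polymorphism is placed per site from the PRF class probabilities at
    n = 2 * n_individuals chromosomes; genotype configurations follow a
    multivariate hypergeometric split of derived copies among individuals.
    Substituted sites stay monomorphic for the focal (derived) base.  IBD
    tracts force homozygosity by copying one haplotype over the other.
    """
    cfg = truth.config
    n_ind = cfg.n_individuals
    if n_ind < 2:
        raise ValueError("need at least 2 individuals")
    n_chrom = 2 * n_ind
    samples = [f"s{j + 1:02d}" for j in range(n_ind)]
    regimes, buckets = _site_regimes(bundle, class_map, truth)
    engine = SfsEngine.get(n_chrom)
    shapes = np.vstack([
        engine.sfs([0.0])[0] if dfe.neutral
        else engine.gamma_sfs(dfe.shape, dfe.mean)
        for dfe, _, _ in buckets])                   # (B, n_chrom-1)
    cum = np.cumsum(shapes, axis=1)
    tot = cum[:, -1]

    table = VariantTable.allocate(
        samples, {c: np.arange(len(s), dtype=np.int64)
                  for c, s in bundle.sequences.items()})
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)   # A<->T, C<->G

    for contig, seq in bundle.sequences.items():
        d = table.arrays(contig)
        L = len(seq)
        from .divergence import encode_seq
        ref = encode_seq(seq)
        d["ref"][:] = np.where(ref == MISSING, 0, ref)
        ids = regimes[contig]
        sub_here = registry[registry["contig"] == contig]["pos"].to_numpy()
        elev = _elevation(L, sub_here, cfg.mutation_elevation,
                          cfg.mutation_elevation_decay)
        elev = elev * _regional_theta_field(L, cfg.theta_regional_sd,
                                            cfg.theta_regional_scale, rng)
        p_poly = np.minimum(cfg.theta * elev * tot[ids], 0.9)
        u = rng.random(L)
        # substituted sites may also segregate; they are then not fixed in
        # the sample and the fixed-substitution restriction drops them
        poly_idx = np.flatnonzero(u < p_poly)
        # conditional class draw: derived multiplicity 1..n-1
        v = u[poly_idx] / p_poly[poly_idx]
        der = np.empty(poly_idx.size, dtype=np.int64)
        for b in np.unique(ids[poly_idx]):
            sel = ids[poly_idx] == b
            der[sel] = 1 + np.searchsorted(cum[b] / tot[b], v[sel],
                                           side="right")
        der = np.clip(der, 1, n_chrom - 1)
        # genotypes: split derived copies among individuals
        gt = d["gt"]
        two = np.full(n_ind, 2)
        for k, site in enumerate(poly_idx):
            copies = rng.multivariate_hypergeometric(two, int(der[k]))
            gt[site] = copies
        # alternate allele base (any base != ref)
        alt = (ref[poly_idx] + rng.integers(1, 4, size=poly_idx.size)) % 4
        d["alt"][poly_idx] = alt
        d["n_alts"][poly_idx] = 1
        tri = rng.random(poly_idx.size) < cfg.triallelic_fraction
        d["n_alts"][poly_idx[tri]] = 2
        # IBD: copy one haplotype over the other
        for t in truth.ibd_tracts:
            if t.contig != contig:
                continue
            j = samples.index(t.sample)
            in_tract = (poly_idx >= t.start) & (poly_idx < t.end)
            het = in_tract & (gt[poly_idx, j] == 1)
            pick = rng.integers(0, 2, size=int(het.sum())) * 2
            gt[poly_idx[het], j] = pick.astype(np.int8)
        # quality fields
        qual = rng.normal(150.0, 25.0, size=L).clip(min=90.0)
        low = rng.random(L) < cfg.low_qual_fraction
        qual[low] = rng.uniform(20.0, 89.5, size=int(low.sum()))
        if cfg.bad_region_fraction > 0:
            blen = int(cfg.bad_region_fraction * L)
            bstart = int(rng.integers(0, max(L - blen, 1)))
            bad = np.zeros(L, bool)
            bad[bstart:bstart + blen] = rng.random(blen) < 0.85
            qual[bad] = rng.uniform(20.0, 89.5, size=int(bad.sum()))
        d["qual"][:] = qual
        dels = np.zeros(L, dtype=np.float32)
        has_dels = rng.random(L) < cfg.dels_fraction
        dels[has_dels] = rng.uniform(0.02, 0.5, size=int(has_dels.sum()))
        d["dels"][:] = dels
        d["dp"][:] = rng.poisson(cfg.mean_depth, size=(L, n_ind))
        # PLs at polymorphic sites
        plb = np.zeros((poly_idx.size, n_ind), dtype=np.int16)
        pls = (40.0 + rng.exponential(60.0, size=(poly_idx.size, n_ind))
               ).astype(np.int16)
        fail = rng.random(poly_idx.size) < cfg.pl_fail_fraction
        which = rng.integers(0, n_ind, size=poly_idx.size)
        fail_best = fail & (rng.random(poly_idx.size) < 0.5)
        rows = np.flatnonzero(fail_best)
        plb[rows, which[rows]] = rng.integers(1, 11, size=rows.size)
        rows = np.flatnonzero(fail & ~fail_best)
        pls[rows, which[rows]] = rng.integers(5, 40, size=rows.size)
        d["pl_best"][poly_idx] = plb
        d["pl_second"][poly_idx] = pls
    return table


def place_ibd_tracts(config: SimConfig, bundle: GenomeBundle,
                     rng: np.random.Generator) -> list[IBDTract]:
    tracts = []
    contigs = list(bundle.sequences)
    for k in range(config.n_ibd_tracts):
        sample = f"s{k + 1:02d}"
        contig = contigs[k % len(contigs)]
        L = len(bundle.sequences[contig])
        tl = min(config.ibd_tract_len, L)
        start = int(rng.integers(0, max(L - tl, 1)))
        tracts.append(IBDTract(sample, contig, start, start + tl, 1.0))
    return tracts


# ---------------------------------------------------------------------------
# sweep troughs
# ---------------------------------------------------------------------------

def inject_sweep_troughs(table: VariantTable, registry: pd.DataFrame,
                         class_map: ClassMap, truth: SimTruth,
                         rng: np.random.Generator) -> VariantTable:
    """Thin polymorphic 4-fold sites around recent adaptive fixations.

    Each trough-bearing substitution independently removes a nearby
    polymorphism with probability depth * exp(-dist/decay); survival under
    overlapping troughs is therefore multiplicative.  Nonadaptive
    substitutions leave diversity untouched.
    """
    cfg = truth.config
    depth, decay = cfg.trough_depth, cfg.trough_decay
    if not 0.0 <= depth <= 1.0:
        raise ValueError("trough depth must lie in [0, 1]")
    if depth == 0.0:
        return table
    cutoff = max(int(6 * decay), 1)
    for contig in table.contigs:
        d = table.arrays(contig)
        anchors = registry[(registry["contig"] == contig)
                           & registry["recent"]]["pos"].to_numpy()
        if anchors.size == 0:
            continue
        four = class_map.classes[contig] == SiteClass.four_fold
        poly = np.any(d["gt"] > 0, axis=1)
        cand = np.flatnonzero(four & poly)
        if cand.size == 0:
            continue
        log_surv = np.zeros(cand.size)
        for a in anchors:
            near = (cand >= a - cutoff) & (cand <= a + cutoff)
            dist = np.abs(cand[near] - a)
            p = depth * np.exp(-dist / decay)
            log_surv[near] += np.log1p(-np.minimum(p, 1.0 - 1e-12))
        removed = rng.random(cand.size) > np.exp(log_surv)
        idx = cand[removed]
        d["gt"][idx] = 0
        d["alt"][idx] = 255
        d["n_alts"][idx] = 0
        d["pl_best"][idx] = -1
        d["pl_second"][idx] = -1
    return table


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(gene_ids: list[str], config: SimConfig,
                        rng: np.random.Generator
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Log-normal FPKM per gene and the per-gene selection multiplier.

    A configured fraction of genes sits below the downstream 1-FPKM filter;
    among the analyzed genes, the mean |S| of the gene's replacement sites
    scales as exp(coupling * (rank01 - 1/2)) of the expression rank, so
    highly expressed genes evolve under stronger purifying selection.
    """
    n = len(gene_ids)
    low = rng.random(n) < config.low_expression_fraction
    fpkm = np.where(
        low,
        rng.lognormal(math.log(0.2), 1.0, size=n),
        rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sigma, size=n))
    mult = np.ones(n)
    analyzed = fpkm >= 1.0
    if analyzed.sum() > 1 and config.expression_coupling != 0.0:
        order = np.argsort(fpkm[analyzed], kind="stable")
        rank01 = np.empty(order.size)
        rank01[order] = (np.arange(order.size) + 0.5) / order.size
        mult[analyzed] = np.exp(config.expression_coupling * (rank01 - 0.5))
    df = pd.DataFrame({"gene_id": gene_ids, "fpkm_mean": fpkm})
    return df, mult


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig | None = None,
                     seed: int = 1) -> SimulatedDataset:
    """Full synthetic dataset: genome, classes, truth, genotypes,
    alignment, expression.  Deterministic given (config, seed)."""
    cfg = config or default_scenario()
    rng = np.random.default_rng(seed)
    bundle = simulate_genome(cfg, rng)
    class_map = classify_sites(bundle)
    gene_ids = bundle.gene_ids
    expression, mult = simulate_expression(gene_ids, cfg, rng)
    truth = SimTruth(cfg, seed, gene_ids, expression["fpkm_mean"].to_numpy(),
                     mult, [])
    truth.gene_adaptive = (rng.random(len(gene_ids))
                           < cfg.adaptive_gene_fraction)
    truth.ibd_tracts = place_ibd_tracts(cfg, bundle, rng)
    alignment, registry = simulate_divergence_triplet(bundle, class_map,
                                                      truth, rng)
    truth.registry = registry
    table = simulate_population(bundle, class_map, truth, registry, rng)
    inject_sweep_troughs(table, registry, class_map, truth, rng)
    if cfg.polarization_error > 0:
        _corrupt_polarization(table, alignment, cfg.polarization_error, rng)
    return SimulatedDataset(bundle, class_map, truth, table, alignment,
                            expression)


def _corrupt_polarization(table: VariantTable, aln: TripletAlignment,
                          frac: float, rng: np.random.Generator) -> None:
    """Swap the outgroup base to the derived allele at a fraction of
    polymorphic sites, emulating ancestral-state misassignment."""
    for contig in table.contigs:
        d = table.arrays(contig)
        poly = np.flatnonzero((d["n_alts"] == 1)
                              & np.any(d["gt"] > 0, axis=1))
        hit = poly[rng.random(poly.size) < frac]
        aln.outgroup1[contig][hit] = d["alt"][hit]
        aln.outgroup2[contig][hit] = d["alt"][hit]
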