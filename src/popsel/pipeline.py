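"""Stage orchestration: chains filtering, IBD, spectra, divergence, DFE,
sweep scan and expression analyses over in-memory inputs, and carries the
per-stage bookkeeping (kept/dropped counts) the CLI logs and writes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .afs import AFS
from .annotate import ANALYZED_CLASSES, ClassMap, CnsCategory, SiteClass
from .config import RunConfig
from .dfe import (BlockData, DfeAlphaBootstrap, bootstrap_dfe_alpha)
from .divergence import (DivergenceCall, TripletAlignment,
                         call_lineage_substitutions, class_divergence,
                         gene_dnds, gene_index, restrict_to_fixed)
from .expression import (ExpressionBins, GeneSelectionData, bin_genes,
                         correlate_dnds_expression, per_bin_selection)
from .filters import (build_afs, detect_ibd, grouped_afs, region_pass_filter,
                      site_pass_masks)
from .genome import GenomeBundle
from .stats import diversity_summary
from .sweeps import run_contrasts, sweep_site_data
from .variants import VariantTable

logger = logging.getLogger(__name__)

__all__ = ["filter_stage", "ibd_stage", "divergence_stage", "afs_stage",
           "make_block_data", "gene_selection_data", "fixed_registry",
           "selected_class_mask"]


def filter_stage(table: VariantTable, cfg: RunConfig
                 ) -> tuple[dict, dict]:
    """Apply filters (1)-(5) plus the 20 kb region filter.

    Returns (keep_mask, poly_pass) per contig; ``keep_mask`` excludes sites
    in failed regions.
    """
    keep, poly = {}, {}
    fc = cfg.filters
    for contig in table.contigs:
        pass_mask, poly_pass = site_pass_masks(table, contig, fc)
        contig_len = int(table.arrays(contig)["pos"].max()) + 1
        excluded = region_pass_filter(pass_mask, contig_len,
                                      cfg.region_window,
                                      cfg.region_min_frac)
        keep[contig] = pass_mask & ~excluded
        poly[contig] = poly_pass & ~excluded
        logger.info("%s: region filter excluded %d sites; %d kept",
                    contig, int(excluded.sum()), int(keep[contig].sum()))
    return keep, poly


def ibd_stage(table: VariantTable, poly_pass: dict, cfg: RunConfig):
    tracts = detect_ibd(table, poly_pass, cfg.filters)
    logger.info("IBD: %d tracts flagged", len(tracts))
    return tracts


def divergence_stage(aln: TripletAlignment, table: VariantTable,
                     class_map: ClassMap, bundle: GenomeBundle,
                     keep_mask: dict, cfg: RunConfig):
    """Substitution calling, fixed-in-sample restriction, per-class
    divergence and per-gene dN/dS."""
    call = call_lineage_substitutions(aln, flank=cfg.mask_flank)
    fixed = restrict_to_fixed(call, table, keep_mask,
                              cfg.fixed_min_chromosomes)
    fixed_df = fixed_registry(fixed, class_map)
    per_class = class_divergence(call, class_map)
    dnds = gene_dnds(call, class_map, bundle)
    return call, fixed, fixed_df, per_class, dnds


def fixed_registry(fixed: dict[str, np.ndarray],
                   class_map: ClassMap) -> pd.DataFrame:
    rows = []
    for contig, mask in fixed.items():
        pos = np.flatnonzero(mask)
        rows.append(pd.DataFrame({
            "contig": contig, "pos": pos,
            "site_class": [SiteClass(c).name
                           for c in class_map.classes[contig][pos]],
            "cns_category": [CnsCategory(c).name
                             for c in class_map.cns[contig][pos]]}))
    if not rows:
        return pd.DataFrame(columns=["contig", "pos", "site_class",
                                     "cns_category"])
    return pd.concat(rows, ignore_index=True)


def afs_stage(table: VariantTable, class_map: ClassMap,
              call: DivergenceCall, tracts, keep_mask: dict,
              cfg: RunConfig, rng: np.random.Generator):
    spectra = build_afs(table, class_map, call.ancestral, tracts,
                        keep_mask, cfg.filters, rng)
    cns_spectra = build_afs(table, class_map, call.ancestral, tracts,
                            keep_mask, cfg.filters, rng, by_cns=True)
    return spectra, cns_spectra


def diversity_stage(table: VariantTable, class_map: ClassMap, tracts,
                    keep_mask: dict, cfg: RunConfig,
                    rng: np.random.Generator):
    """Spectra for diversity statistics: polarization-free (the reference
    base stands in for the ancestral state), so unpolarizable sites are
    retained; theta_w, pi and Tajima's D only use folded information."""
    anc = {}
    for c in table.contigs:
        d = table.arrays(c)
        a = np.full(class_map.classes[c].size, 4, dtype=np.uint8)
        a[d["pos"]] = d["ref"]
        anc[c] = a
    return build_afs(table, class_map, anc, tracts, keep_mask,
                     cfg.filters, rng)


def selected_class_mask(class_map: ClassMap, name: str
                        ) -> dict[str, np.ndarray]:
    """Per-contig site mask for a selected-class name: a primary class,
    a CNS category, or 'cns_all' (any CNS)."""
    out = {}
    for contig, cls in class_map.classes.items():
        cns = class_map.cns[contig]
        if name == "cns_all":
            out[contig] = cns != CnsCategory.none
        elif name in CnsCategory.__members__:
            out[contig] = cns == CnsCategory[name]
        elif name in SiteClass.__members__:
            # CNS-flagged sites are analyzed as CNS, not as their host class
            out[contig] = ((cls == SiteClass[name])
                           & (cns == CnsCategory.none))
        else:
            raise ValueError(f"unknown site class {name!r}")
    return out


def make_block_data(table: VariantTable, class_map: ClassMap,
                    call: DivergenceCall, tracts, keep_mask: dict,
                    selected: str, cfg: RunConfig,
                    rng: np.random.Generator) -> BlockData:
    """Per-10kb-block sufficient statistics for the joint DFE/alpha
    bootstrap of one selected class against the 4-fold neutral class."""
    sel_mask = selected_class_mask(class_map, selected)
    neu_mask = selected_class_mask(class_map, SiteClass.four_fold.name)
    offsets, n_blocks = {}, 0
    for contig in table.contigs:
        L = class_map.classes[contig].size
        nb = max(1, int(np.ceil(L / cfg.block_size)))
        offsets[contig] = n_blocks
        n_blocks += nb

    def groups_for(mask):
        g = {}
        for contig in table.contigs:
            L = class_map.classes[contig].size
            ids = (np.arange(L) // cfg.block_size) + offsets[contig]
            g[contig] = np.where(mask[contig], ids, -1).astype(np.int64)
        return g

    fc = cfg.filters
    neu_counts = grouped_afs(table, call.ancestral, tracts, keep_mask,
                             groups_for(neu_mask), n_blocks, fc, rng)
    sel_counts = grouped_afs(table, call.ancestral, tracts, keep_mask,
                             groups_for(sel_mask), n_blocks, fc, rng)

    def div_counts(mask):
        sites = np.zeros(n_blocks)
        subs = np.zeros(n_blocks)
        for contig in table.contigs:
            L = class_map.classes[contig].size
            ids = (np.arange(L) // cfg.block_size) + offsets[contig]
            ok = call.assessed[contig] & mask[contig]
            sites += np.bincount(ids[ok], minlength=n_blocks)
            sub = ok & call.substitution[contig]
            subs += np.bincount(ids[sub], minlength=n_blocks)
        return sites, subs

    neu_sites, neu_subs = div_counts(neu_mask)
    sel_sites, sel_subs = div_counts(sel_mask)
    return BlockData(neu_counts, sel_counts, neu_sites, neu_subs,
                     sel_sites, sel_subs)


def gene_selection_data(table: VariantTable, class_map: ClassMap,
                        bundle: GenomeBundle, call: DivergenceCall,
                        tracts, keep_mask: dict, cfg: RunConfig,
                        rng: np.random.Generator) -> GeneSelectionData:
    """Per-gene 0-fold and 4-fold spectra and divergence counts."""
    gidx, genes = gene_index(bundle)
    G = len(genes)
    fc = cfg.filters

    def groups_for(target: SiteClass):
        g = {}
        for contig in table.contigs:
            cls = class_map.classes[contig]
            g[contig] = np.where(cls == target, gidx[contig],
                                 -1).astype(np.int64)
        return g

    zero_afs = grouped_afs(table, call.ancestral, tracts, keep_mask,
                           groups_for(SiteClass.zero_fold), G, fc, rng)
    four_afs = grouped_afs(table, call.ancestral, tracts, keep_mask,
                           groups_for(SiteClass.four_fold), G, fc, rng)

    def div_counts(target: SiteClass):
        sites = np.zeros(G)
        subs = np.zeros(G)
        for contig in table.contigs:
            cls = class_map.classes[contig]
            gi = gidx[contig]
            ok = call.assessed[contig] & (cls == target) & (gi >= 0)
            sites += np.bincount(gi[ok], minlength=G)
            sub = ok & call.substitution[contig]
            subs += np.bincount(gi[sub], minlength=G)
        return sites, subs

    z_sites, z_subs = div_counts(SiteClass.zero_fold)
    f_sites, f_subs = div_counts(SiteClass.four_fold)
    return GeneSelectionData(genes, cfg.target_n, zero_afs, four_afs,
                             z_sites, z_subs, f_sites, f_subs)
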