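"""Seedable synthetic panels with the population structure the pipeline assumes.

The generator emulates, in miniature, a multi-population inbred crop panel:
per-gene haplotype pools with geometric-decay frequencies (one predominant
haplotype plus a tail of rare ones), a configurable fraction of
population-private haplotypes, monomorphic genes with no CDS SNPs at all,
and modern-variety populations derived from a landrace pool through a
breeding bottleneck - a retained fraction of the landrace haplotypes, novel
single-crossover recombinants, and occasional promotion of a landrace-rare
haplotype to major frequency.  Phenotypes are additive haplotype effects
plus Gaussian noise.  Every draw comes from one seeded generator, so a
config reproduces its panel byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .io import (GT_ALT, GT_REF, GeneModel, InputError, PhenotypeTable,
                 PopulationPartition, Site, VariantSet)

BASES = "ACGT"


class ConfigError(InputError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class PopulationSpec:
    """One simulated population.  A population with a ``parent`` derives its
    haplotype pool from that (landrace) population through the bottleneck."""

    name: str
    size: int
    status: str = gio.LAN
    parent: str | None = None


@dataclass
class TraitEffect:
    """Additive effect (in residual-SD units when noise_sd = 1) planted on
    one haplotype of one gene for one trait.  ``hap_rank`` indexes the first
    base population's haplotype pool in frequency order (0 = predominant),
    so small ranks plant the effect on a major haplotype."""

    gene: str
    trait: str
    hap_rank: int
    effect: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 26
    sites_per_gene: tuple[int, int] = (6, 16)
    fraction_monomorphic: float = 2 / 26
    populations: list[PopulationSpec] = field(default_factory=lambda: [
        PopulationSpec("Xian", 180), PopulationSpec("Geng", 77),
        PopulationSpec("Aus", 22), PopulationSpec("Bas", 19),
    ])
    divergence: float = 0.3  # fraction of population-private haplotypes
    lan_hap_pool_size: int = 12
    hap_freq_decay: float = 0.7  # geometric ratio of pool frequencies
    bottleneck_retain: float = 0.5  # fraction of parent haplotypes kept in MV
    recomb_rate: float = 0.02  # P(an MV accession carries a novel recombinant)
    rare_promotion_rate: float = 0.05  # P(a LAN-rare hap becomes major in MV)
    trait_effects: list[TraitEffect] = field(default_factory=list)
    traits: list[str] = field(default_factory=lambda: ["trait1"])
    noise_sd: float = 1.0
    baseline: float = 100.0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for frac, name in [(self.fraction_monomorphic, "fraction_monomorphic"),
                           (self.divergence, "divergence"),
                           (self.bottleneck_retain, "bottleneck_retain"),
                           (self.recomb_rate, "recomb_rate"),
                           (self.rare_promotion_rate, "rare_promotion_rate")]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]: {frac}")
        if any(p.size < 1 for p in self.populations):
            raise ConfigError("population sizes must be >= 1")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")
        for p in self.populations:
            if p.parent is not None and p.parent not in names:
                raise ConfigError(f"population {p.name}: unknown parent {p.parent}")


@dataclass
class SimulatedPanel:
    """A generated panel plus the ground truth behind it."""

    config: SimulationConfig
    variants: VariantSet
    genes: list[GeneModel]
    partition: PopulationPartition
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "panel.vcf",
            "bed": out / "genes.bed",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.json",
        }
        gio.write_vcf(self.variants, paths["vcf"])
        gio.write_gene_models_bed(self.genes, paths["bed"])
        gio.write_population_metadata(self.partition, paths["metadata"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1)
        return paths


def _distinct_strings(rng: np.random.Generator, n_sites: int, count: int,
                      refs: Sequence[str], alts: Sequence[str]) -> list[str]:
    """``count`` distinct allele strings over the gene's site alleles."""
    if count > 2 ** n_sites:
        raise ConfigError(
            f"pool of {count} haplotypes infeasible with {n_sites} sites"
        )
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < count:
        x = int(rng.integers(0, 2 ** n_sites))
        if x not in seen:
            seen.add(x)
            out.append(x)
    strings = []
    for x in out:
        chars = [alts[j] if (x >> j) & 1 else refs[j] for j in range(n_sites)]
        strings.append("".join(chars))
    return strings


def _geometric_freqs(n: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(n)
    return w / w.sum()


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate a full panel (variants, gene models, partition, truth).

    Per polymorphic gene each base (landrace) population receives a
    haplotype pool mixing shared and private allele strings, ordered at
    random and given geometric-decay frequencies; derived (modern-variety)
    populations keep a uniform ``bottleneck_retain`` fraction of the parent
    pool, occasionally promote a parent-rare haplotype to a major rank, and
    accessions carry a novel single-crossover recombinant with probability
    ``recomb_rate``.  Genotypes are homozygous biallelic SNP calls.  The
    first ``round(fraction_monomorphic * n_genes)`` genes are monomorphic
    (zero segregating CDS sites).
    """
    rng = np.random.default_rng(config.seed)
    n_mono = int(round(config.fraction_monomorphic * config.n_genes))

    accessions: list[str] = []
    pop_label: dict[str, str] = {}
    status: dict[str, str] = {}
    for spec in config.populations:
        for k in range(spec.size):
            acc = f"{spec.name}_{k + 1:04d}"
            accessions.append(acc)
            pop_label[acc] = spec.name
            status[acc] = spec.status if spec.status in {gio.LAN, gio.MV} else gio.UNKNOWN
    partition = PopulationPartition(population=pop_label, breeding_status=status)

    base_pops = [p for p in config.populations if p.parent is None]
    derived_pops = [p for p in config.populations if p.parent is not None]

    genes: list[GeneModel] = []
    sites: list[Site] = []
    gt_columns: list[np.ndarray] = []
    truth_genes: dict[str, dict] = {}
    truth_assign: dict[str, dict[str, str]] = {}

    gene_span, cds_len = 10_000, 2_000
    lo, hi = config.sites_per_gene
    for g_idx in range(config.n_genes):
        gid = f"gene{g_idx + 1:03d}"
        gstart = g_idx * gene_span
        genes.append(GeneModel(gid, config.chrom, "+", [(gstart, gstart + cds_len)]))
        monomorphic = g_idx < n_mono

        if monomorphic:
            truth_genes[gid] = {"n_sites": 0, "monomorphic": True,
                                "pools": {}, "shared_order": []}
            truth_assign[gid] = {a: "" for a in accessions}
            continue

        n_sites = int(rng.integers(lo, hi + 1))
        positions = np.sort(rng.choice(cds_len, size=n_sites, replace=False)) + gstart + 1
        refs, alts = [], []
        for _ in range(n_sites):
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            refs.append(str(ref))
            alts.append(str(alt))
        gene_sites = [Site(config.chrom, int(p), r, a)
                      for p, r, a in zip(positions, refs, alts)]

        pool_size = config.lan_hap_pool_size
        n_shared = int(round((1.0 - config.divergence) * pool_size))
        n_private = pool_size - n_shared
        total = n_shared + n_private * len(base_pops)
        strings = _distinct_strings(rng, n_sites, total, refs, alts)
        shared = strings[:n_shared]
        private_chunks = [
            strings[n_shared + i * n_private: n_shared + (i + 1) * n_private]
            for i in range(len(base_pops))
        ]

        pools: dict[str, tuple[list[str], np.ndarray]] = {}
        for i, spec in enumerate(base_pops):
            members = shared + private_chunks[i]
            order = rng.permutation(len(members))
            ordered = [members[j] for j in order]
            pools[spec.name] = (ordered, _geometric_freqs(len(ordered),
                                                          config.hap_freq_decay))
        for spec in derived_pops:
            parent_haps, parent_freqs = pools[spec.parent]
            n_keep = max(1, int(round(config.bottleneck_retain * len(parent_haps))))
            keep_idx = np.sort(rng.choice(len(parent_haps), size=n_keep, replace=False))
            kept = [parent_haps[j] for j in keep_idx]  # parent frequency order
            if rng.random() < config.rare_promotion_rate:
                rare_idx = [j for j, f in enumerate(parent_freqs) if f < 0.01]
                if rare_idx:
                    promoted = parent_haps[int(rng.choice(rare_idx))]
                    if promoted in kept:
                        kept.remove(promoted)
                    kept.insert(min(1, len(kept)), promoted)
            pools[spec.name] = (kept, _geometric_freqs(len(kept),
                                                       config.hap_freq_decay))

        assign: dict[str, str] = {}
        for spec in config.populations:
            haps, freqs = pools[spec.name]
            members = [a for a in accessions if pop_label[a] == spec.name]
            draws = rng.choice(len(haps), size=len(members), p=freqs)
            for acc, j in zip(members, draws):
                hap = haps[int(j)]
                if spec.parent is not None and n_sites >= 2 and \
                        rng.random() < config.recomb_rate:
                    pa, pb = rng.choice(len(haps), size=2, p=freqs)
                    cut = int(rng.integers(1, n_sites))
                    hap = haps[int(pa)][:cut] + haps[int(pb)][cut:]
                assign[acc] = hap

        for j, site in enumerate(gene_sites):
            col = np.array(
                [GT_REF if assign[a][j] == site.ref else GT_ALT for a in accessions],
                dtype="<U1",
            )
            sites.append(site)
            gt_columns.append(col)

        truth_genes[gid] = {
            "n_sites": n_sites,
            "monomorphic": False,
            "pools": {name: {h: float(f) for h, f in zip(*pools[name])}
                      for name in pools},
            "shared_order": shared,
        }
        truth_assign[gid] = assign

    variants = VariantSet(
        sites=sites,
        accessions=accessions,
        genotypes=(np.column_stack(gt_columns) if gt_columns
                   else np.empty((len(accessions), 0), dtype="<U1")),
    )
    truth = {
        "config": _config_dict(config),
        "genes": truth_genes,
        "assignments": truth_assign,
        "effects": [asdict(e) for e in _resolved_effects(config, truth_genes)],
    }
    return SimulatedPanel(config=config, variants=variants, genes=genes,
                          partition=partition, truth=truth)


@dataclass
class _ResolvedEffect:
    gene: str
    trait: str
    hap_string: str
    effect: float


def _resolved_effects(config: SimulationConfig,
                      truth_genes: dict) -> list[_ResolvedEffect]:
    base_pop = next((p.name for p in config.populations if p.parent is None), None)
    out = []
    for eff in config.trait_effects:
        if eff.gene not in truth_genes:
            raise ConfigError(f"trait effect references unknown gene {eff.gene}")
        pool = list(truth_genes[eff.gene]["pools"].get(base_pop, {}))
        if not 0 <= eff.hap_rank < len(pool):
            raise ConfigError(
                f"trait effect on {eff.gene}: hap_rank {eff.hap_rank} outside "
                f"the {base_pop} pool of {len(pool)} haplotypes"
            )
        if eff.trait not in config.traits:
            raise ConfigError(f"trait effect references unknown trait {eff.trait}")
        out.append(_ResolvedEffect(eff.gene, eff.trait, pool[eff.hap_rank],
                                   eff.effect))
    return out


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["sites_per_gene"] = list(d["sites_per_gene"])
    return d


def simulate_phenotypes(panel: SimulatedPanel, seed: int | None = None) -> PhenotypeTable:
    """Phenotypes from the panel's truth record: for each trait,
    baseline + sum of planted effects of carried haplotypes + N(0, noise_sd).

    ``seed`` defaults to ``config.seed + 1`` so genotypes and phenotypes
    come from distinct but reproducible streams.
    """
    config = panel.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    accs = panel.variants.accessions
    effects = [_ResolvedEffect(**e) for e in panel.truth["effects"]]

    values = pd.DataFrame(config.baseline, index=accs, columns=config.traits,
                          dtype=float)
    for eff in effects:
        assign = panel.truth["assignments"][eff.gene]
        carriers = [a for a in accs if assign[a] == eff.hap_string]
        values.loc[carriers, eff.trait] += eff.effect
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=values.shape)
        values += noise
    return PhenotypeTable(values=values)


def scenario_presets(name: str) -> SimulationConfig:
    """Named study conditions.

    ``A_diversity``
        26 genes (2 monomorphic) in four populations whose sizes mirror the
        Xian/Geng/Aus/Bas panel in miniature; exercises calling, diversity
        classes and differentiation end to end.
    ``B_bottleneck``
        A 700-accession landrace population and a 300-accession
        modern-variety population derived from it with bottleneck retention
        0.5, recombination rate 0.02 and rare-promotion rate 0.05, over 24
        polymorphic genes; exercises the lost/new/retained accounting.
    ``C_association``
        1,000 accessions, one polymorphic gene, one planted 1-SD haplotype
        effect on one trait; exercises association and favorable-allele
        mining.
    """
    if name == "A_diversity":
        return SimulationConfig(
            n_genes=26, fraction_monomorphic=2 / 26,
            populations=[
                PopulationSpec("Xian", 180), PopulationSpec("Geng", 77),
                PopulationSpec("Aus", 22), PopulationSpec("Bas", 19),
            ],
        )
    if name == "B_bottleneck":
        return SimulationConfig(
            n_genes=24, fraction_monomorphic=0.0,
            populations=[
                PopulationSpec("Xian_LAN", 700, gio.LAN),
                PopulationSpec("Xian_MV", 300, gio.MV, parent="Xian_LAN"),
            ],
            bottleneck_retain=0.5, recomb_rate=0.02, rare_promotion_rate=0.05,
        )
    if name == "C_association":
        return SimulationConfig(
            n_genes=1, fraction_monomorphic=0.0,
            populations=[PopulationSpec("Panel", 1000)],
            trait_effects=[TraitEffect("gene001", "trait1", 1, 1.0)],
            traits=["trait1"], noise_sd=1.0,
        )
    raise ConfigError(f"unknown scenario preset {name!r}")
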