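"""Gene-CDS-haplotype (gcHap) construction and diversity statistics.

A gcHap is the ordered string of alleles an accession carries at every SNP
site inside a gene's coding sequence.  In a selfing crop each accession is
effectively homozygous, so one haplotype per accession per gene is the unit
of allelic identity.  This module builds those haplotypes, assigns stable
frequency-ranked labels (Hap1, Hap2, ...), and computes the per-scope
summary statistics used downstream: haplotype frequencies, Shannon's
equitability (Pielou evenness) E_H, diversity classes, the major-haplotype
set and the predominant haplotype with its frequency F(P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GT_ALT, GT_HET, GT_MISS, GT_REF, GeneModel, InputError, VariantSet

#: heterozygote / missing resolution policies for haplotype calling
POLICIES = ("major-allele", "drop-accession", "missing-code")

#: symbol used for unresolved sites under the "missing-code" policy
MISSING_SYMBOL = "N"

#: diversity class names, in increasing-diversity order
DIVERSITY_CLASSES = ("HK", "low", "medium-low", "medium-high", "high")


@dataclass
class GcHapTable:
    """Per-gene haplotype calls: ordered CDS SNP sites, accession->label
    assignment, label->allele-string map and labeling-scope frequencies.

    Labels are assigned once, over the labeling scope (by default the full
    panel), by descending frequency with ties broken by lexicographically
    smaller allele string; sub-scope analyses reuse these labels so that
    "Hap1" means the same allele string everywhere.
    """

    gene_id: str
    sites: list  # ordered list of io.Site
    assignments: pd.Series  # index accession -> haplotype label
    haplotypes: dict[str, str]  # label -> allele string
    frequencies: pd.Series  # label -> frequency in the labeling scope

    def hap_frequencies(self, scope: Sequence[str] | None = None) -> pd.Series:
        """Haplotype frequencies within ``scope`` (default: labeling scope).

        Only haplotypes observed in the scope appear; frequencies sum to 1.
        """
        if scope is None:
            return self.frequencies.copy()
        scope = [a for a in scope if a in self.assignments.index]
        if not scope:
            raise InputError(f"gene {self.gene_id}: empty scope after policy exclusions")
        counts = self.assignments.loc[scope].value_counts()
        freqs = counts / counts.sum()
        # keep global label order (Hap1, Hap2, ...) for reproducible output
        order = [lab for lab in self.frequencies.index if lab in freqs.index]
        return freqs.loc[order]

    def carriers(self, label: str, scope: Sequence[str] | None = None) -> list[str]:
        sel = self.assignments[self.assignments == label]
        if scope is not None:
            scope_set = set(scope)
            sel = sel[sel.index.isin(scope_set)]
        return list(sel.index)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class DiversityStats:
    """Diversity summary for one gene within one accession scope."""

    gene_id: str
    scope: str
    gchapn: int
    major_set: list[str]
    majorn: int
    e_h: float
    diversity_class: str
    predominant: str
    f_p: float


def extract_cds_snps(variants: VariantSet, gene: GeneModel) -> VariantSet:
    """Restrict a variant set to SNPs falling inside the gene's CDS intervals,
    ordered by position.  An empty result is allowed."""
    idx = [
        i for i, s in enumerate(variants.sites)
        if s.chrom == gene.chrom and gene.contains(s.pos)
    ]
    idx.sort(key=lambda i: variants.sites[i].pos)
    return variants.subset_sites(idx)


def _resolve_strings(gene_variants: VariantSet, policy: str) -> tuple[list[str], list[str]]:
    """Return (retained accessions, allele strings) under the stated policy."""
    if policy not in POLICIES:
        raise InputError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    G = gene_variants.genotypes
    n_acc, n_sites = G.shape

    # per-site majority allele over unambiguous calls; ties go to ref
    major = []
    for j in range(n_sites):
        col = G[:, j]
        n_ref = int(np.sum(col == GT_REF))
        n_alt = int(np.sum(col == GT_ALT))
        major.append(GT_ALT if n_alt > n_ref else GT_REF)

    accs, strings = [], []
    for i, acc in enumerate(gene_variants.accessions):
        chars = []
        drop = False
        for j in range(n_sites):
            code = G[i, j]
            site = gene_variants.sites[j]
            if code == GT_REF:
                chars.append(site.ref)
            elif code == GT_ALT:
                chars.append(site.alt)
            elif policy == "major-allele":
                c = major[j]
                chars.append(site.ref if c == GT_REF else site.alt)
            elif policy == "drop-accession":
                drop = True
                break
            else:  # missing-code: ambiguous calls become a third symbol
                chars.append(MISSING_SYMBOL)
        if drop:
            continue
        accs.append(acc)
        strings.append("".join(chars))
    return accs, strings


def call_gchaps(gene_variants: VariantSet, gene_id: str = "",
                policy: str = "major-allele") -> GcHapTable:
    """Assign each accession its gcHap at one gene and label haplotypes by
    descending frequency (ties: lexicographically smaller allele string).

    Heterozygous and missing codes are resolved per ``policy``:

    ``major-allele`` (default)
        replace with the site's majority allele across accessions,
    ``drop-accession``
        exclude the accession from this gene's scope,
    ``missing-code``
        keep a third symbol, so partially missing strings form their own
        haplotypes.

    A gene with zero CDS SNPs yields exactly one haplotype (the empty
    string) covering all accessions.
    """
    if gene_variants.n_accessions == 0:
        raise InputError("call_gchaps: empty accession set")
    accs, strings = _resolve_strings(gene_variants, policy)
    if not accs:
        raise InputError(
            f"gene {gene_id or '?'}: no accession retained under policy {policy!r}"
        )

    counts: dict[str, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    ranked = sorted(counts, key=lambda s: (-counts[s], s))
    label_of = {s: f"Hap{k + 1}" for k, s in enumerate(ranked)}

    n = len(accs)
    freqs = pd.Series(
        {label_of[s]: counts[s] / n for s in ranked},
        index=[label_of[s] for s in ranked], dtype=float,
    )
    return GcHapTable(
        gene_id=gene_id,
        sites=list(gene_variants.sites),
        assignments=pd.Series([label_of[s] for s in strings], index=accs),
        haplotypes={label_of[s]: s for s in ranked},
        frequencies=freqs,
    )


def shannon_equitability(p: Sequence[float]) -> float:
    """Shannon's equitability E_H = H / ln(S), the Shannon entropy of the
    haplotype frequency vector normalized by its maximum (Pielou evenness).

    E_H is 0 for a single haplotype, 1 for a uniform distribution, and lies
    in [0, 1] otherwise.  ``p`` must be a proper frequency vector (positive,
    summing to 1 within 1e-9).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.any(p <= 0):
        raise InputError("shannon_equitability: frequencies must be positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InputError(f"shannon_equitability: frequencies sum to {p.sum()!r}, not 1")
    s = p.size
    if s == 1:
        return 0.0
    h = float(-(p * np.log(p)).sum())
    return min(h / math.log(s), 1.0)


def classify_diversity(e_h: float, gchapn: int) -> str:
    """Diversity class from E_H and haplotype count.

    HK ("house-keeping" in this pipeline's sense: no CDS SNP variation,
    single haplotype) when gcHapN = 1; otherwise binned on E_H at
    0.05 / 0.3 / 0.7 (low, medium-low, medium-high, high; the top class is
    closed at 1).
    """
    if not 0.0 <= e_h <= 1.0:
        raise InputError(f"E_H out of [0,1]: {e_h}")
    if gchapn == 1:
        return "HK"
    if e_h < 0.05:
        return "low"
    if e_h < 0.3:
        return "medium-low"
    if e_h < 0.7:
        return "medium-high"
    return "high"


def major_gchaps(p: pd.Series, threshold: float = 0.01,
                 min_count: int | None = None, scope_size: int | None = None) -> list[str]:
    """Labels of major haplotypes, ordered by descending frequency.

    By default a haplotype is major when its frequency is >= ``threshold``
    (inclusive).  Alternatively an absolute carrier-count rule is available:
    pass ``min_count`` together with ``scope_size`` and a haplotype is major
    when it is carried by at least ``min_count`` accessions.
    """
    if min_count is not None:
        if scope_size is None:
            raise InputError("min_count mode requires scope_size")
        keep = p * scope_size >= min_count - 1e-9
    else:
        if not 0.0 < threshold < 1.0:
            raise InputError(f"major threshold must be in (0,1): {threshold}")
        keep = p >= threshold - 1e-12
    sel = p[keep]
    return list(sel.sort_values(ascending=False, kind="stable").index)


def predominant_gchap(p: pd.Series, haplotypes: dict[str, str] | None = None) -> tuple[str, float]:
    """The haplotype of maximum frequency and that frequency F(P).

    Ties are broken by lexicographically smaller allele string (falling
    back to the label when strings are unavailable).
    """
    if p.empty:
        raise InputError("predominant_gchap: empty frequency vector")
    top = float(p.max())
    tied = [lab for lab in p.index if p[lab] >= top - 1e-15]
    if haplotypes:
        tied.sort(key=lambda lab: haplotypes.get(lab, lab))
    else:
        tied.sort()
    return tied[0], top


def diversity_stats(table: GcHapTable, scope: Sequence[str] | None = None,
                    scope_name: str = "panel",
                    major_threshold: float = 0.01) -> DiversityStats:
    """All per-scope diversity summaries for one gene in one call."""
    p = table.hap_frequencies(scope)
    e_h = shannon_equitability(p.to_numpy())
    major = major_gchaps(p, threshold=major_threshold)
    pred, f_p = predominant_gchap(p, table.haplotypes)
    return DiversityStats(
        gene_id=table.gene_id,
        scope=scope_name,
        gchapn=int(p.size),
        major_set=major,
        majorn=len(major),
        e_h=e_h,
        diversity_class=classify_diversity(e_h, int(p.size)),
        predominant=pred,
        f_p=f_p,
    )


def call_panel(variants: VariantSet, genes: Sequence[GeneModel],
               policy: str = "major-allele") -> dict[str, GcHapTable]:
    """Call gcHaps for every gene in a panel; returns gene_id -> table."""
    return {
        g.gene_id: call_gchaps(extract_cds_snps(variants, g), g.gene_id, policy)
        for g in genes
    }


def haplotype_table_frame(tables: dict[str, GcHapTable]) -> pd.DataFrame:
    """Long-format accession x gene haplotype assignment table."""
    rows = []
    for gid, t in tables.items():
        for acc, lab in t.assignments.items():
            rows.append((acc, gid, lab, t.haplotypes[lab]))
    return pd.DataFrame(rows, columns=["accession", "gene", "haplotype", "allele_string"])


def diversity_frame(stats: Sequence[DiversityStats]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene_id, "scope": s.scope, "gcHapN": s.gchapn,
            "majorN": s.majorn, "E_H": s.e_h, "class": s.diversity_class,
            "predominant": s.predominant, "F_P": s.f_p,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)
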