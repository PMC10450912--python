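"""Per-population diversity summaries and between-population differentiation.

Differentiation between two populations at a gene is measured with Nei's
genetic identity

    I = sum(p_i * q_i) / sqrt(sum(p_i^2) * sum(q_i^2))

computed on the two populations' haplotype frequency vectors aligned on the
union of their haplotype sets (absences zero-padded).  I = 1 means identical
frequency distributions, I = 0 disjoint haplotype pools; values below 0.35
are flagged as strong differentiation (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DiversityStats, GcHapTable, diversity_stats
from .io import InputError, PopulationPartition

#: default "strong differentiation" cutoff on Nei's identity
STRONG_DIFFERENTIATION = 0.35


@dataclass
class NeiIdentityMatrix:
    """Symmetric Nei-identity matrix over populations for one gene."""

    gene_id: str
    populations: list[str]
    identity: pd.DataFrame  # square, index/columns = populations
    threshold: float = STRONG_DIFFERENTIATION

    @property
    def flags(self) -> pd.DataFrame:
        """Strong-differentiation flags: True where I_Nei < threshold."""
        f = self.identity < self.threshold
        np.fill_diagonal(f.values, False)
        return f

    def to_long(self) -> pd.DataFrame:
        rows = []
        pops = self.populations
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                val = float(self.identity.loc[a, b])
                rows.append((self.gene_id, a, b, val, bool(val < self.threshold)))
        return pd.DataFrame(rows, columns=["gene", "popA", "popB", "I_Nei", "strong"])


def population_stats(table: GcHapTable, partition: PopulationPartition,
                     major_threshold: float = 0.01,
                     populations: list[str] | None = None) -> list[DiversityStats]:
    """One :class:`DiversityStats` per (gene, population), plus one for the
    whole panel.  Haplotype counts are of haplotypes observed in that
    population only; labels stay those of the panel-wide labeling scope."""
    pops = populations if populations is not None else partition.populations
    out = [diversity_stats(table, None, "panel", major_threshold)]
    for pop in pops:
        members = partition.members(pop)  # raises on unknown/empty
        out.append(diversity_stats(table, members, pop, major_threshold))
    return out


def nei_identity(p, q) -> float:
    """Nei's genetic identity of two frequency vectors on a shared haplotype
    universe (zero entries mark absences)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError("nei_identity: vectors must share the haplotype universe")
    np_, nq = float(np.dot(p, p)), float(np.dot(q, q))
    if np_ == 0.0 or nq == 0.0:
        raise InputError("nei_identity: zero frequency vector")
    return float(np.dot(p, q) / np.sqrt(np_ * nq))


def aligned_frequencies(table: GcHapTable, scopes: dict[str, list[str]]) -> pd.DataFrame:
    """Per-scope frequency vectors aligned on the union haplotype universe.

    Each column is one scope's within-scope frequencies (summing to 1), with
    zeros for haplotypes absent from that scope.
    """
    per_scope = {name: table.hap_frequencies(members) for name, members in scopes.items()}
    universe = [lab for lab in table.frequencies.index
                if any(lab in f.index for f in per_scope.values())]
    return pd.DataFrame(
        {name: f.reindex(universe, fill_value=0.0) for name, f in per_scope.items()},
        index=universe,
    )


def pairwise_identity_matrix(table: GcHapTable, partition: PopulationPartition,
                             populations: list[str] | None = None,
                             threshold: float = STRONG_DIFFERENTIATION) -> NeiIdentityMatrix:
    """All-pairs Nei identity between populations at one gene."""
    pops = populations if populations is not None else partition.populations
    if len(pops) < 2:
        raise InputError("pairwise_identity_matrix: need >= 2 populations")
    freqs = aligned_frequencies(table, {p: partition.members(p) for p in pops})
    m = pd.DataFrame(np.eye(len(pops)), index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            val = nei_identity(freqs[a].to_numpy(), freqs[b].to_numpy())
            m.loc[a, b] = m.loc[b, a] = val
    return NeiIdentityMatrix(table.gene_id, list(pops), m, threshold)
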