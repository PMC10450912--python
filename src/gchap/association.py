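"""Haplotype-trait association and favorable-allele mining.

Accessions carrying a gene's major haplotypes are grouped by haplotype and
their trait values compared with a one-way ANOVA; pairwise differences are
summarised as a compact letter display (Tukey HSD by default, Duncan's
multiple range test as an alternative).  Associations with p below a strong
threshold (default 1e-7) are flagged.  The *favorable* haplotype is the one
with the most desirable (by default highest) mean trait value; the
*unfavorable* haplotype is the major haplotype of lowest frequency, and the
two extremes are contrasted with a Welch t-test.  Favorable-haplotype
frequencies can be tabulated per subpopulation for breeding use.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GcHapTable, major_gchaps
from .io import InputError, PhenotypeTable, PopulationPartition

logger = logging.getLogger("gchap")

STRONG_P = 1e-7


@dataclass
class AssociationResult:
    """Association of one gene's major haplotypes with one trait."""

    gene_id: str
    trait: str
    groups: pd.DataFrame  # index hap label; columns n, mean, sd
    f_stat: float
    p_value: float
    letters: dict[str, str]
    strong: bool
    testable: bool
    favorable: str | None = None
    unfavorable: str | None = None
    pred_vs_unfav: tuple[float, float] | None = None  # (mean diff, p)


def anova_across_haps(groups: Mapping[str, Sequence[float]],
                      min_group_n: int = 2) -> tuple[float, float, pd.DataFrame, bool]:
    """One-way ANOVA of trait values across haplotype groups.

    Groups with fewer than ``min_group_n`` non-missing values are dropped
    (logged).  Returns (F, p, per-group summary, testable); with fewer than
    two eligible groups the result is flagged not testable (F = nan, p = nan).
    Identical groups (zero between- and within-group variance) give
    F = 0, p = 1.
    """
    clean: dict[str, np.ndarray] = {}
    for lab, vals in groups.items():
        v = np.asarray(pd.Series(vals, dtype=float).dropna())
        if v.size >= min_group_n:
            clean[lab] = v
        else:
            logger.info("anova: dropped group %s (n=%d < %d)", lab, v.size, min_group_n)

    summary = pd.DataFrame(
        {
            lab: {"n": v.size, "mean": float(v.mean()),
                  "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}
            for lab, v in clean.items()
        }
    ).T
    if len(clean) < 2:
        return float("nan"), float("nan"), summary, False

    arrays = list(clean.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all values equal: no signal, no noise
        return 0.0, 1.0, summary, True
    grand = pooled.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in arrays)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    df_b = len(arrays) - 1
    df_w = pooled.size - len(arrays)
    if ssw == 0:
        return float("inf"), 0.0, summary, True
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p, summary, True


def _tukey_pairwise_p(clean: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    labs = list(clean)
    n_total = sum(v.size for v in clean.values())
    k = len(labs)
    df_w = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in clean.values()) / df_w
    out = {}
    for a, b in itertools.combinations(labs, 2):
        va, vb = clean[a], clean[b]
        if mse == 0:
            p = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            se = np.sqrt(mse / 2 * (1 / va.size + 1 / vb.size))
            q = abs(va.mean() - vb.mean()) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        out[(a, b)] = out[(b, a)] = p
    return out


def _duncan_nonsig(clean: dict[str, np.ndarray], alpha: float) -> dict[tuple[str, str], bool]:
    """Duncan's multiple range test: compare means sorted by value; the
    critical value for two means spanning p ranks uses the protection level
    1 - (1 - alpha)^(p-1) of the studentized range."""
    labs = sorted(clean, key=lambda l: clean[l].mean())
    k = len(labs)
    n_total = sum(v.size for v in clean.values())
    df_w = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in clean.values()) / df_w
    nonsig = {}
    for i, j in itertools.combinations(range(k), 2):
        a, b = labs[i], labs[j]
        va, vb = clean[a], clean[b]
        span = j - i + 1
        if mse == 0:
            ns = va.mean() == vb.mean()
        else:
            alpha_p = 1 - (1 - alpha) ** (span - 1)
            q_crit = stats.studentized_range.isf(alpha_p, span, df_w)
            # harmonic mean group size handles unbalanced groups
            nh = 2 / (1 / va.size + 1 / vb.size)
            lsr = q_crit * np.sqrt(mse / nh)
            ns = abs(va.mean() - vb.mean()) <= lsr
        nonsig[(a, b)] = nonsig[(b, a)] = bool(ns)
    return nonsig


def letter_groups(groups: Mapping[str, Sequence[float]], method: str = "tukey",
                  alpha: float = 0.05, min_group_n: int = 2) -> dict[str, str]:
    """Compact letter display over haplotype groups.

    Groups sharing a letter are not significantly different at ``alpha``
    under the chosen pairwise procedure ({"tukey", "duncan"}).  Letters are
    maximal sets of mutually non-different groups, lettered from the
    highest group mean down.
    """
    if method not in {"tukey", "duncan"}:
        raise InputError(f"unknown letter method {method!r}")
    clean = {
        lab: np.asarray(pd.Series(v, dtype=float).dropna())
        for lab, v in groups.items()
    }
    clean = {lab: v for lab, v in clean.items() if v.size >= min_group_n}
    labs = list(clean)
    if len(labs) == 1:
        return {labs[0]: "a"}
    if not labs:
        return {}

    if method == "tukey":
        pairp = _tukey_pairwise_p(clean)
        nonsig = {pair: p >= alpha for pair, p in pairp.items()}
    else:
        nonsig = _duncan_nonsig(clean, alpha)

    # maximal cliques of the "not significantly different" graph; every
    # group belongs to >= 1 clique, two groups share a letter iff nonsig
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(labs)
    g.add_edges_from(pair for pair, ns in nonsig.items() if ns and pair[0] < pair[1])
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(clean[l].mean() for l in c), sorted(c)))
    letters: dict[str, str] = {lab: "" for lab in labs}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, clique in enumerate(cliques):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for lab in clique:
            letters[lab] += ch
    return {lab: "".join(sorted(s)) for lab, s in letters.items()}


def strong_association_flag(p: float, threshold: float = STRONG_P) -> bool:
    """True when p is strictly below the strong-association threshold."""
    if not 0.0 <= p <= 1.0:
        raise InputError(f"p out of [0,1]: {p}")
    return p < threshold


def favorable_hap(group_summary: pd.DataFrame, direction: str = "max") -> str:
    """Haplotype with the extreme mean trait value (default highest).

    Ties are broken by larger carrier count, then lexicographic label.
    """
    if group_summary.empty:
        raise InputError("favorable_hap: no eligible haplotype")
    if direction not in {"max", "min"}:
        raise InputError(f"direction must be 'max' or 'min': {direction!r}")
    sign = -1.0 if direction == "max" else 1.0
    ranked = sorted(
        group_summary.index,
        key=lambda lab: (sign * group_summary.loc[lab, "mean"],
                         -group_summary.loc[lab, "n"], lab),
    )
    return ranked[0]


def unfavorable_hap(freqs: pd.Series, major_set: Sequence[str]) -> str | None:
    """The major haplotype of lowest frequency (ties: lexicographically
    smaller label); None when the major set is empty."""
    majors = [m for m in major_set if m in freqs.index]
    if not majors:
        return None
    return min(majors, key=lambda lab: (freqs[lab], lab))


def compare_predominant_vs_unfavorable(pred_values: Sequence[float],
                                       unfav_values: Sequence[float]) -> tuple[float, float] | None:
    """Welch t-test contrast of the predominant vs unfavorable haplotype
    groups; returns (mean of predominant minus mean of unfavorable, p), or
    None when either group has n < 2.  Identical groups give (0, 1)."""
    a = np.asarray(pd.Series(pred_values, dtype=float).dropna())
    b = np.asarray(pd.Series(unfav_values, dtype=float).dropna())
    if a.size < 2 or b.size < 2:
        return None
    diff = float(a.mean() - b.mean())
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # zero variance in both groups but different means
        return diff, 0.0
    return diff, float(p)


def trait_groups(table: GcHapTable, phenos: PhenotypeTable, trait: str,
                 scope: Sequence[str] | None = None,
                 major_threshold: float = 0.01) -> tuple[dict[str, pd.Series], pd.Series, list[str]]:
    """Trait values grouped by major haplotype (non-major carriers excluded).

    Returns (groups, scope frequencies, major set).
    """
    p = table.hap_frequencies(scope)
    majors = major_gchaps(p, threshold=major_threshold)
    values = phenos.trait(trait)
    groups = {}
    for lab in majors:
        carriers = [a for a in table.carriers(lab, scope) if a in values.index]
        groups[lab] = values.loc[carriers].dropna()
    return groups, p, majors


def associate(table: GcHapTable, phenos: PhenotypeTable, trait: str,
              scope: Sequence[str] | None = None,
              major_threshold: float = 0.01, min_group_n: int = 2,
              strong_threshold: float = STRONG_P, alpha: float = 0.05,
              letter_method: str = "tukey",
              direction: str = "max") -> AssociationResult:
    """Full association of one gene with one trait: ANOVA across major
    haplotype groups, letter display, strong-association flag, favorable and
    unfavorable calls, and the predominant-vs-unfavorable contrast."""
    groups, p, majors = trait_groups(table, phenos, trait, scope, major_threshold)
    f, pv, summary, testable = anova_across_haps(groups, min_group_n)
    letters = letter_groups(groups, method=letter_method, alpha=alpha,
                            min_group_n=min_group_n) if testable else {}

    fav = favorable_hap(summary, direction) if not summary.empty else None
    unfav = unfavorable_hap(p, majors)
    pred = p.index[p.to_numpy().argmax()] if len(p) else None

    contrast = None
    if unfav is not None and pred is not None and pred != unfav:
        contrast = compare_predominant_vs_unfavorable(
            groups.get(pred, pd.Series(dtype=float)),
            groups.get(unfav, pd.Series(dtype=float)),
        )
    return AssociationResult(
        gene_id=table.gene_id, trait=trait, groups=summary,
        f_stat=f, p_value=pv, letters=letters,
        strong=testable and strong_association_flag(pv, strong_threshold),
        testable=testable, favorable=fav, unfavorable=unfav,
        pred_vs_unfav=contrast,
    )


def favorable_frequency_table(favorable: str, table: GcHapTable,
                              partition: PopulationPartition,
                              subpopulations: Sequence[str] | None = None) -> pd.DataFrame:
    """Frequency and carrier count of the favorable haplotype in each
    subpopulation (population labels are used when no subpopulation labels
    exist).  Empty subpopulations are flagged with an undefined frequency."""
    labels = partition.subpopulation or partition.population
    if subpopulations is None:
        subpopulations = []
        for v in labels.values():
            if v and v not in subpopulations:
                subpopulations.append(v)
    rows = []
    for sub in subpopulations:
        members = [a for a, s in labels.items() if s == sub]
        scoped = [a for a in members if a in table.assignments.index]
        carriers = [a for a in scoped if table.assignments[a] == favorable]
        if not scoped:
            rows.append((table.gene_id, favorable, sub, 0, float("nan"), True))
        else:
            rows.append((table.gene_id, favorable, sub, len(carriers),
                         len(carriers) / len(scoped), False))
    return pd.DataFrame(
        rows, columns=["gene", "haplotype", "subpopulation",
                       "n_carriers", "frequency", "undefined"],
    )


def tally_percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Share of positive cases as a percentage (e.g. strong associations
    over gene x trait cases), rounded to ``ndigits`` decimals."""
    if denominator <= 0:
        raise InputError("tally_percent: non-positive denominator")
    return round(100.0 * numerator / denominator, ndigits)
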