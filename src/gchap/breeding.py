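"""Breeding-impact accounting between landraces (LAN) and modern varieties (MV).

For each gene the haplotype pools of a landrace scope and a modern-variety
scope are compared: haplotypes present in LAN but absent from MV are *lost*,
present in MV but absent from LAN are *new*, present in both *retained*.
The same accounting on each scope's own major-haplotype set distinguishes
promotions (rare in LAN, major in MV -> "new major") from genuinely novel
haplotypes.  The landrace-predominant haplotype's frequency shift between
the scopes is tested with a 2x2 chi-square on carrier counts.  Panel-level
summaries express mean per-locus losses/gains as percentages of stated
population-wide per-locus means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GcHapTable, major_gchaps, predominant_gchap
from .io import InputError


@dataclass
class BreedingImpact:
    """Lost / new / retained haplotype accounting for one gene."""

    gene_id: str
    lost: set[str]
    new: set[str]
    retained: set[str]
    lost_major: set[str]
    new_major: set[str]
    retained_major: set[str]
    lan_gchapn: int
    mv_gchapn: int
    lan_majorn: int
    mv_majorn: int
    f_p_lan: float
    f_p_mv: float
    delta_f_p: float
    chi2: float
    p_value: float
    degenerate: bool = False
    predominant: str = ""


@dataclass
class ImpactSummary:
    """Panel-level means and percentage accounting across loci."""

    n_loci: int
    mean_lost: float
    mean_new: float
    mean_retained: float
    mean_lost_major: float
    mean_new_major: float
    mean_retained_major: float
    pct_lost: float
    pct_new: float
    pct_lost_major: float
    pct_new_major: float
    n_significant_increase: int = 0
    n_significant_decrease: int = 0
    undefined_pct: bool = False


def compare_populations(table: GcHapTable, lan_scope: Sequence[str],
                        mv_scope: Sequence[str],
                        major_threshold: float = 0.01) -> BreedingImpact:
    """Lost/new/retained haplotype sets (all and major) between a landrace
    and a modern-variety scope, plus the predominant-frequency shift test.

    Major sets are computed within each scope on its own frequencies, so a
    haplotype rare (< threshold) in LAN but frequent in MV counts as *new
    major* even though it is *retained* in the all-haplotype accounting; a
    *retained major* must be major in both scopes.
    """
    lan_scope, mv_scope = list(lan_scope), list(mv_scope)
    if not lan_scope or not mv_scope:
        raise InputError("compare_populations: empty scope")
    if set(lan_scope) & set(mv_scope):
        raise InputError("compare_populations: scopes must be disjoint")

    p_lan = table.hap_frequencies(lan_scope)
    p_mv = table.hap_frequencies(mv_scope)
    lan_set, mv_set = set(p_lan.index), set(p_mv.index)
    lan_major = set(major_gchaps(p_lan, major_threshold))
    mv_major = set(major_gchaps(p_mv, major_threshold))

    shift = predominant_shift(table, lan_scope, mv_scope)
    return BreedingImpact(
        gene_id=table.gene_id,
        lost=lan_set - mv_set,
        new=mv_set - lan_set,
        retained=lan_set & mv_set,
        lost_major=lan_major - mv_major,
        new_major=mv_major - lan_major,
        retained_major=lan_major & mv_major,
        lan_gchapn=len(lan_set),
        mv_gchapn=len(mv_set),
        lan_majorn=len(lan_major),
        mv_majorn=len(mv_major),
        f_p_lan=shift["f_p_lan"],
        f_p_mv=shift["f_p_mv"],
        delta_f_p=shift["delta"],
        chi2=shift["chi2"],
        p_value=shift["p"],
        degenerate=shift["degenerate"],
        predominant=shift["predominant"],
    )


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]].

    Without continuity correction (default) this is the closed form
    n (ad - bc)^2 / (r1 r2 c1 c2); a zero margin is degenerate and reported
    as (0, 1).
    """
    tab = np.array([[a, b], [c, d]], dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=correction)
    return float(chi2), float(p)


def predominant_shift(table: GcHapTable, lan_scope: Sequence[str],
                      mv_scope: Sequence[str], correction: bool = False) -> dict:
    """Frequency of the LAN-predominant haplotype in both scopes with a 2x2
    carrier/non-carrier chi-square (no continuity correction by default).

    A degenerate table (zero margin, e.g. the haplotype absent from both or
    fixed in both) is flagged and reported with p = 1.
    """
    p_lan = table.hap_frequencies(lan_scope)
    pred, f_p_lan = predominant_gchap(p_lan, table.haplotypes)
    p_mv = table.hap_frequencies(mv_scope)
    f_p_mv = float(p_mv.get(pred, 0.0))

    n_lan, n_mv = len(set(lan_scope) & set(table.assignments.index)), \
        len(set(mv_scope) & set(table.assignments.index))
    car_lan = int(round(f_p_lan * n_lan))
    car_mv = int(round(f_p_mv * n_mv))
    a, b = car_lan, n_lan - car_lan
    c, d = car_mv, n_mv - car_mv
    degenerate = (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0)
    chi2, p = chi2_2x2(a, b, c, d, correction=correction)
    return {
        "predominant": pred,
        "f_p_lan": float(f_p_lan),
        "f_p_mv": f_p_mv,
        "delta": f_p_mv - float(f_p_lan),
        "chi2": chi2,
        "p": p,
        "degenerate": degenerate,
    }


def percentage_accounting(mean_lost: float, mean_new: float,
                          mean_lost_major: float, mean_new_major: float,
                          pop_mean_gchapn: float, pop_mean_majorn: float,
                          ndigits: int = 1) -> dict[str, float]:
    """Express mean per-locus lost/new counts as percentages of the
    population-wide per-locus means, rounded to ``ndigits`` decimals.

    The denominators are the population-wide (not LAN- or MV-specific)
    mean haplotype and major-haplotype counts per locus.
    """
    if pop_mean_gchapn <= 0 or pop_mean_majorn <= 0:
        raise InputError("percentage_accounting: zero denominator")
    return {
        "pct_lost": round(100.0 * mean_lost / pop_mean_gchapn, ndigits),
        "pct_new": round(100.0 * mean_new / pop_mean_gchapn, ndigits),
        "pct_lost_major": round(100.0 * mean_lost_major / pop_mean_majorn, ndigits),
        "pct_new_major": round(100.0 * mean_new_major / pop_mean_majorn, ndigits),
    }


def percent_change(before: float, after: float, ndigits: int = 1) -> float:
    """Relative change (after - before) / before as a percentage."""
    if before == 0:
        raise InputError("percent_change: zero baseline")
    return round(100.0 * (after - before) / before, ndigits)


def summarize_impact(impacts: Sequence[BreedingImpact],
                     pop_mean_gchapn: float, pop_mean_majorn: float,
                     alpha: float = 0.05) -> ImpactSummary:
    """Panel-level summary of per-locus breeding impact.

    Mean lost/new/retained counts are arithmetic means over the supplied
    loci; the percentage fields divide mean lost/new by the supplied
    population-wide per-locus means.  Significant predominant-frequency
    shifts are counted at ``alpha``, increases and decreases separately.
    """
    if not impacts:
        raise InputError("summarize_impact: no loci")
    mean_lost = float(np.mean([len(i.lost) for i in impacts]))
    mean_new = float(np.mean([len(i.new) for i in impacts]))
    mean_ret = float(np.mean([len(i.retained) for i in impacts]))
    mean_lost_major = float(np.mean([len(i.lost_major) for i in impacts]))
    mean_new_major = float(np.mean([len(i.new_major) for i in impacts]))
    mean_ret_major = float(np.mean([len(i.retained_major) for i in impacts]))

    undefined = pop_mean_gchapn <= 0 or pop_mean_majorn <= 0
    if undefined:
        pct = dict(pct_lost=float("nan"), pct_new=float("nan"),
                   pct_lost_major=float("nan"), pct_new_major=float("nan"))
    else:
        pct = percentage_accounting(mean_lost, mean_new, mean_lost_major,
                                    mean_new_major, pop_mean_gchapn, pop_mean_majorn)

    n_inc = sum(1 for i in impacts
                if not i.degenerate and i.p_value < alpha and i.delta_f_p > 0)
    n_dec = sum(1 for i in impacts
                if not i.degenerate and i.p_value < alpha and i.delta_f_p < 0)
    return ImpactSummary(
        n_loci=len(impacts),
        mean_lost=mean_lost, mean_new=mean_new, mean_retained=mean_ret,
        mean_lost_major=mean_lost_major, mean_new_major=mean_new_major,
        mean_retained_major=mean_ret_major,
        n_significant_increase=n_inc, n_significant_decrease=n_dec,
        undefined_pct=undefined, **pct,
    )


def impact_frame(impacts: Sequence[BreedingImpact]) -> pd.DataFrame:
    """Per-gene impact table mirroring the LAN/MV comparison layout:
    counts with major counts in parentheses."""
    rows = []
    for i in impacts:
        rows.append({
            "gene": i.gene_id,
            "LAN_gcHapN": f"{i.lan_gchapn} ({i.lan_majorn})",
            "MV_gcHapN": f"{i.mv_gchapn} ({i.mv_majorn})",
            "lost": f"{len(i.lost)} ({len(i.lost_major)})",
            "new": f"{len(i.new)} ({len(i.new_major)})",
            "retained": f"{len(i.retained)} ({len(i.retained_major)})",
            "predominant": i.predominant,
            "F_P_LAN": i.f_p_lan,
            "F_P_MV": i.f_p_mv,
            "delta_F_P": i.delta_f_p,
            "chi2": i.chi2,
            "p": i.p_value,
            "degenerate": i.degenerate,
        })
    return pd.DataFrame(rows)
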