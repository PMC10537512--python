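"""Heterotic group assignment from combining-ability effects.

Two-tester rules:

* SCA method: a line goes to the group mapped to tester T when its SCA with
  T is positive, its SCA with the other tester is negative, its best
  testcross mean is not significantly below the T1 x T2 check mean (LSD
  criterion), and its SCA magnitude clears the trait threshold; otherwise it
  stays unassigned.
* HSGCA method: every line is assigned — to the group of the tester with the
  positive HSGCA when signs differ, otherwise to the group of the tester
  picked by the tie-break (default: the smaller value, i.e. smallest
  positive / largest negative).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from heterokit.combining import CrossMeansTable, EffectsTable

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: default minimum |SCA| magnitudes per trait
DEFAULT_MIN_SCA = {"grain_yield": 100.0, "pva": 0.05}


@dataclass
class GroupingConfig:
    #: group a line is assigned to when its effect with this tester is
    #: positive (i.e. the opposite of the tester's own group)
    tester_to_group: dict[str, str] = field(
        default_factory=lambda: {"T1": "HGB", "T2": "HGA"}
    )
    alpha: float = 0.05
    min_sca_magnitude: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_SCA)
    )
    tie_break: str = "min_value"  # or "max_value"

    def __post_init__(self) -> None:
        if len(self.tester_to_group) != 2:
            raise ValueError("exactly two testers must be mapped")
        if len(set(self.tester_to_group.values())) != 2:
            raise ValueError("testers must map to two distinct groups")
        if self.tie_break not in ("min_value", "max_value"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")

    @property
    def testers(self) -> list[str]:
        return list(self.tester_to_group)


@dataclass
class HeteroticAssignment:
    trait: str
    method: str  # "SCA" or "HSGCA"
    groups: dict[str, str]  # line -> HGA/HGB/unassigned
    support: pd.DataFrame  # per-line effect values and decision inputs

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.groups.values():
            out[g] = out.get(g, 0) + 1
        return out

    def __post_init__(self) -> None:
        if self.method == "HSGCA" and UNASSIGNED in self.groups.values():
            raise ValueError("HSGCA method must assign every line")


@dataclass
class ConcordanceReport:
    methods: list[str]
    spearman: pd.DataFrame  # method x method rho
    p_values: pd.DataFrame
    agreement_pct: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "spearman": self.spearman.to_dict(),
            "p_values": self.p_values.to_dict(),
            "agreement_pct": self.agreement_pct.to_dict(),
        }


def assign_sca(
    effects: EffectsTable,
    means: CrossMeansTable,
    check_mean: float,
    lsd_value: float,
    config: GroupingConfig,
    trait: str | None = None,
) -> HeteroticAssignment:
    """SCA sign-opposition rule with the testcross-mean-vs-check condition.

    ``check_mean`` is the T1 x T2 check-cross mean; "not significantly
    different or greater" is operationalized as best testcross mean >=
    check_mean - lsd_value.
    """
    if check_mean is None or not np.isfinite(check_mean):
        raise ValueError("check_mean is required for SCA-based grouping")
    trait = trait or effects.trait
    t1, t2 = config.testers
    threshold = config.min_sca_magnitude.get(trait, 0.0)

    groups: dict[str, str] = {}
    rows = []
    for line in effects.lines:
        s1, s2 = effects.sca[(line, t1)], effects.sca[(line, t2)]
        best_mean = max(means.cross_means[(line, t1)], means.cross_means[(line, t2)])
        mean_ok = best_mean >= check_mean - lsd_value
        magnitude_ok = max(abs(s1), abs(s2)) >= threshold
        if magnitude_ok and mean_ok and s1 > 0 and s2 < 0:
            group = config.tester_to_group[t1]
        elif magnitude_ok and mean_ok and s2 > 0 and s1 < 0:
            group = config.tester_to_group[t2]
        else:
            group = UNASSIGNED
        groups[line] = group
        rows.append(
            {
                "line": line,
                f"sca_{t1}": s1,
                f"sca_{t2}": s2,
                f"mean_{t1}": means.cross_means[(line, t1)],
                f"mean_{t2}": means.cross_means[(line, t2)],
                "check_mean": check_mean,
                "lsd": lsd_value,
                "group": group,
            }
        )
    return HeteroticAssignment(
        trait=trait, method="SCA", groups=groups, support=pd.DataFrame(rows)
    )


def assign_hsgca(
    effects: EffectsTable,
    config: GroupingConfig,
    trait: str | None = None,
) -> HeteroticAssignment:
    """HSGCA sign rule; assigns every line (two-tester method)."""
    if len(effects.testers) != 2:
        raise ValueError("HSGCA grouping is defined for exactly two testers")
    trait = trait or effects.trait
    t1, t2 = config.testers

    groups: dict[str, str] = {}
    rows = []
    for line in effects.lines:
        h1, h2 = effects.hsgca[(line, t1)], effects.hsgca[(line, t2)]
        if h1 > 0 >= h2:
            chosen = t1
        elif h2 > 0 >= h1:
            chosen = t2
        else:
            # both positive or both non-positive: tie-break on value
            if h1 == h2:
                chosen = t1  # deterministic: first tester in config order
                logger.info(
                    "exact HSGCA tie for line %s (%g); broke by tester order",
                    line,
                    h1,
                )
            elif config.tie_break == "min_value":
                chosen = t1 if h1 < h2 else t2
            else:
                chosen = t1 if h1 > h2 else t2
        group = config.tester_to_group[chosen]
        groups[line] = group
        rows.append(
            {"line": line, f"hsgca_{t1}": h1, f"hsgca_{t2}": h2, "group": group}
        )
    return HeteroticAssignment(
        trait=trait, method="HSGCA", groups=groups, support=pd.DataFrame(rows)
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        rho = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += rho >= obs - 1e-12
        total += 1
    return count / total


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with exact permutation p for n <= 10, t-approx above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= 10:
        return rho, float(_spearman_exact_p(x, y))
    return rho, float(stats.spearmanr(x, y).pvalue)


def compare_methods(
    assignments: dict[str, HeteroticAssignment],
    scores: dict[str, dict[str, float]],
) -> ConcordanceReport:
    """Pairwise Spearman correlation of per-line scores and group agreement.

    ``scores`` maps method -> line -> numeric score (by convention the
    line's effect value with the first tester under that method).
    Unassigned lines count as disagreement but stay in the denominator.
    """
    methods = list(assignments)
    if len(methods) < 2:
        raise ValueError("need >= 2 methods to compare")
    line_sets = [set(a.groups) for a in assignments.values()]
    if any(s != line_sets[0] for s in line_sets[1:]):
        raise ValueError("mismatched line sets across methods")
    lines = sorted(line_sets[0])

    rho = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    pval = pd.DataFrame(np.zeros((len(methods), len(methods))), index=methods, columns=methods)
    agree = pd.DataFrame(np.full((len(methods), len(methods)), 100.0), index=methods, columns=methods)
    for a, b in itertools.combinations(methods, 2):
        xa = np.array([scores[a][l] for l in lines])
        xb = np.array([scores[b][l] for l in lines])
        r, p = spearman_with_p(xa, xb)
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
        same = sum(
            assignments[a].groups[l] == assignments[b].groups[l]
            and assignments[a].groups[l] != UNASSIGNED
            for l in lines
        )
        agree.loc[a, b] = agree.loc[b, a] = 100.0 * same / len(lines)
    return ConcordanceReport(
        methods=methods, spearman=rho, p_values=pval, agreement_pct=agree
    )
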