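"""Combining-ability analysis for line x tester trials.

Effects follow the textbook moment formulas on cross means:

    GCA(line)   = line mean - overall mean
    GCA(tester) = tester mean - overall mean
    SCA(l, t)   = cross mean - line mean - tester mean + overall mean
    HSGCA(l, t) = GCA(line) + SCA(l, t)  ( = cross mean - tester mean )

Margins are computed from cross means, not raw plot pooling, so mildly
unbalanced replication does not bias them.  The combined ANOVA uses the
RCBD sequential decomposition Env + Rep(Env) + Hybrid + Hybrid x Env +
Error with Hybrid partitioned into Line + Tester + Line x Tester (and the
interaction likewise); Line, Tester and Line x Tester F-ratios use the
matching x Env mean square as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from heterokit.io import TrialTable


@dataclass
class CrossMeansTable:
    trait: str
    overall_mean: float
    line_means: dict[str, float]
    tester_means: dict[str, float]
    cross_means: dict[tuple[str, str], float]
    n_obs: dict[tuple[str, str], int]
    check_means: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def lines(self) -> list[str]:
        return list(self.line_means)

    @property
    def testers(self) -> list[str]:
        return list(self.tester_means)


@dataclass
class EffectsTable:
    trait: str
    gca_line: dict[str, float]
    gca_tester: dict[str, float]
    sca: dict[tuple[str, str], float]
    hsgca: dict[tuple[str, str], float]
    se_gca_line: float = float("nan")
    se_gca_tester: float = float("nan")
    se_sca: float = float("nan")

    @property
    def lines(self) -> list[str]:
        return list(self.gca_line)

    @property
    def testers(self) -> list[str]:
        return list(self.gca_tester)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for line in self.lines:
            row: dict = {"line": line, "gca": self.gca_line[line]}
            for tester in self.testers:
                row[f"sca_{tester}"] = self.sca[(line, tester)]
                row[f"hsgca_{tester}"] = self.hsgca[(line, tester)]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AnovaTable:
    trait: str
    table: pd.DataFrame  # columns: source, df, ss, ms, F, p
    repeatability: float
    cv_pct: float
    grand_mean: float

    def row(self, source: str) -> pd.Series:
        hit = self.table.loc[self.table["source"] == source]
        if hit.empty:
            raise KeyError(f"no ANOVA row {source!r}")
        return hit.iloc[0]

    @property
    def ms_error(self) -> float:
        return float(self.row("Error")["ms"])

    @property
    def df_error(self) -> int:
        return int(self.row("Error")["df"])


def cell_means(trial: TrialTable, trait: str) -> CrossMeansTable:
    """Per-cross arithmetic means over env x rep observations.

    Missing cells are excluded; margins are averages of cross means.  The
    tester x tester check crosses, when present, are reported separately in
    ``check_means`` and excluded from all margins.
    """
    if trait not in trial.traits:
        raise KeyError(f"trait {trait!r} not in trial (has {trial.traits})")
    data = trial.data
    tc = data.loc[~data["is_check"]]
    grouped = tc.groupby(["line", "tester"])[trait]
    means = grouped.mean()
    counts = grouped.count()

    lines, testers = trial.lines, trial.testers
    missing_cross = [
        (l, t)
        for l in lines
        for t in testers
        if (l, t) not in counts.index or counts.loc[(l, t)] == 0
    ]
    if missing_cross:
        raise ValueError(
            f"crosses with zero observations for {trait!r}: {missing_cross}"
        )

    cross = {(l, t): float(means.loc[(l, t)]) for l in lines for t in testers}
    mat = np.array([[cross[(l, t)] for t in testers] for l in lines])
    line_means = dict(zip(lines, mat.mean(axis=1)))
    tester_means = dict(zip(testers, mat.mean(axis=0)))

    checks = data.loc[data["is_check"]]
    check_means = {
        key: float(val)
        for key, val in checks.groupby(["line", "tester"])[trait].mean().items()
    }
    return CrossMeansTable(
        trait=trait,
        overall_mean=float(mat.mean()),
        line_means={k: float(v) for k, v in line_means.items()},
        tester_means={k: float(v) for k, v in tester_means.items()},
        cross_means=cross,
        n_obs={(l, t): int(counts.loc[(l, t)]) for l in lines for t in testers},
        check_means=check_means,
    )


def estimate_effects(
    means: CrossMeansTable,
    ms_error: float | None = None,
    n_obs_per_cross: int | None = None,
) -> EffectsTable:
    """GCA/SCA/HSGCA from a cross-means table.

    When ``ms_error`` and ``n_obs_per_cross`` (env x rep observations per
    cross) are given, plug-in standard errors for each effect class are
    attached.
    """
    lines, testers = means.lines, means.testers
    if len(lines) < 2 or len(testers) < 2:
        raise ValueError("need >= 2 lines and >= 2 testers")
    mu = means.overall_mean
    gca_line = {l: means.line_means[l] - mu for l in lines}
    gca_tester = {t: means.tester_means[t] - mu for t in testers}
    sca = {
        (l, t): means.cross_means[(l, t)]
        - means.line_means[l]
        - means.tester_means[t]
        + mu
        for l in lines
        for t in testers
    }
    hsgca = {key: gca_line[key[0]] + sca[key] for key in sca}

    se_l = se_t = se_s = float("nan")
    if ms_error is not None and n_obs_per_cross is not None:
        nl, nt = len(lines), len(testers)
        se_l = float(np.sqrt(ms_error / (n_obs_per_cross * nt)))
        se_t = float(np.sqrt(ms_error / (n_obs_per_cross * nl)))
        se_s = float(np.sqrt(ms_error / n_obs_per_cross))
    return EffectsTable(
        trait=means.trait,
        gca_line=gca_line,
        gca_tester=gca_tester,
        sca=sca,
        hsgca=hsgca,
        se_gca_line=se_l,
        se_gca_tester=se_t,
        se_sca=se_s,
    )


def _interaction_ss(cell: np.ndarray, weight: float) -> float:
    """weight x sum of double-centered squared cell means (2-D input)."""
    centered = (
        cell
        - cell.mean(axis=0, keepdims=True)
        - cell.mean(axis=1, keepdims=True)
        + cell.mean()
    )
    return float(weight * (centered**2).sum())


def anova_line_by_tester(trial: TrialTable, trait: str) -> AnovaTable:
    """Combined line x tester ANOVA across environments.

    Requires >= 2 environments and >= 2 reps.  Balanced closed-form
    sequential sums of squares are computed from cell means; mild
    missingness is tolerated by substituting cell means into the balanced
    formulas (documented convention).  Variance components use moment
    estimators truncated at zero; repeatability is entry-mean
    sigma2_h / (sigma2_h + sigma2_he/e + sigma2_err/(r e)).
    """
    data = trial.data.loc[~trial.data["is_check"]].copy()
    data = data.dropna(subset=[trait])
    lines, testers, envs = trial.lines, trial.testers, trial.envs
    nl, nt, ne = len(lines), len(testers), len(envs)
    reps = sorted(data["rep"].unique())
    nr = len(reps)
    if ne < 2:
        raise ValueError("single environment: interaction terms undefined")
    if nr < 2:
        raise ValueError("need >= 2 replicates")

    li = data["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    ti = data["tester"].map({t: i for i, t in enumerate(testers)}).to_numpy()
    ei = data["env"].astype(str).map({e: i for i, e in enumerate(envs)}).to_numpy()
    ri = data["rep"].map({r: i for i, r in enumerate(reps)}).to_numpy()
    y = data[trait].to_numpy(dtype=float)

    sums = np.zeros((nl, nt, ne, nr))
    counts = np.zeros((nl, nt, ne, nr))
    np.add.at(sums, (li, ti, ei, ri), y)
    np.add.at(counts, (li, ti, ei, ri), 1)
    if (counts == 0).any():
        raise ValueError("empty line x tester x env x rep cells")
    cell = sums / counts  # plot-level means (== observations when balanced)

    grand = cell.mean()
    # balanced closed forms on cell means
    ss_env = nl * nt * nr * ((cell.mean(axis=(0, 1, 3)) - grand) ** 2).sum()
    er_means = cell.mean(axis=(0, 1))  # env x rep
    ss_rep = nl * nt * (
        (er_means - er_means.mean(axis=1, keepdims=True)) ** 2
    ).sum()
    h_means = cell.mean(axis=(2, 3))  # line x tester
    ss_hybrid = ne * nr * ((h_means - grand) ** 2).sum()
    ss_line = nt * ne * nr * ((h_means.mean(axis=1) - grand) ** 2).sum()
    ss_tester = nl * ne * nr * ((h_means.mean(axis=0) - grand) ** 2).sum()
    ss_lxt = ss_hybrid - ss_line - ss_tester

    he_means = cell.mean(axis=3)  # line x tester x env
    he_flat = he_means.reshape(nl * nt, ne)
    ss_hxe = _interaction_ss(he_flat, nr)
    ss_lxe = _interaction_ss(he_means.mean(axis=1), nt * nr)
    ss_txe = _interaction_ss(he_means.mean(axis=0), nl * nr)
    ss_lxtxe = ss_hxe - ss_lxe - ss_txe

    ss_total = float(((y - grand) ** 2).sum())
    ss_model = ss_env + ss_rep + ss_hybrid + ss_hxe
    ss_error = max(ss_total - ss_model, 0.0)

    nh = nl * nt
    df = {
        "Environment": ne - 1,
        "Rep(Env)": ne * (nr - 1),
        "Hybrid": nh - 1,
        "Line(GCA)": nl - 1,
        "Tester(GCA)": nt - 1,
        "LinexTester(SCA)": (nl - 1) * (nt - 1),
        "HybridxEnv": (nh - 1) * (ne - 1),
        "LinexEnv": (nl - 1) * (ne - 1),
        "TesterxEnv": (nt - 1) * (ne - 1),
        "LinexTesterxEnv": (nl - 1) * (nt - 1) * (ne - 1),
        "Error": ne * (nr - 1) * (nh - 1),
    }
    if any(v < 0 for v in df.values()):
        raise ValueError("negative degrees of freedom")
    ss = {
        "Environment": ss_env,
        "Rep(Env)": ss_rep,
        "Hybrid": ss_hybrid,
        "Line(GCA)": ss_line,
        "Tester(GCA)": ss_tester,
        "LinexTester(SCA)": ss_lxt,
        "HybridxEnv": ss_hxe,
        "LinexEnv": ss_lxe,
        "TesterxEnv": ss_txe,
        "LinexTesterxEnv": ss_lxtxe,
        "Error": ss_error,
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}

    # F denominators: genetic main/interaction structure vs its xEnv term,
    # interactions and blocking terms vs error
    denom = {
        "Environment": "Error",
        "Rep(Env)": "Error",
        "Hybrid": "HybridxEnv",
        "Line(GCA)": "LinexEnv",
        "Tester(GCA)": "TesterxEnv",
        "LinexTester(SCA)": "LinexTesterxEnv",
        "HybridxEnv": "Error",
        "LinexEnv": "Error",
        "TesterxEnv": "Error",
        "LinexTesterxEnv": "Error",
    }
    rows = []
    for source in df:
        if source == "Error":
            rows.append(
                {"source": source, "df": df[source], "ss": ss[source],
                 "ms": ms[source], "F": np.nan, "p": np.nan}
            )
            continue
        dms = ms[denom[source]]
        ddf = df[denom[source]]
        f = ms[source] / dms if dms > 0 else np.nan
        p = float(stats.f.sf(f, df[source], ddf)) if np.isfinite(f) else np.nan
        rows.append(
            {"source": source, "df": df[source], "ss": ss[source],
             "ms": ms[source], "F": f, "p": p}
        )
    table = pd.DataFrame(rows)

    sigma2_err = ms["Error"]
    sigma2_he = max((ms["HybridxEnv"] - ms["Error"]) / nr, 0.0)
    sigma2_h = max((ms["Hybrid"] - ms["HybridxEnv"]) / (nr * ne), 0.0)
    denom_rep = sigma2_h + sigma2_he / ne + sigma2_err / (nr * ne)
    repeatability = sigma2_h / denom_rep if denom_rep > 0 else 0.0
    cv_pct = 100.0 * np.sqrt(sigma2_err) / grand if grand != 0 else np.nan

    return AnovaTable(
        trait=trait,
        table=table,
        repeatability=float(repeatability),
        cv_pct=float(cv_pct),
        grand_mean=float(grand),
    )


def lsd(anova: AnovaTable, alpha: float, n_obs_per_mean: int) -> float:
    """Least significant difference between two means at level alpha.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha {alpha} outside (0,1)")
    if anova.df_error < 1:
        raise ValueError("error df must be >= 1")
    t_crit = stats.t.ppf(1 - alpha / 2, anova.df_error)
    return float(t_crit * np.sqrt(2 * anova.ms_error / n_obs_per_mean))
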