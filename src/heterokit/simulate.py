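"""Synthetic line x tester trials and structured genotype panels.

Both generators are fully determined by ``SimConfig.seed``; per-generator
substreams are derived deterministically so trial and genotype outputs do
not interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heterokit.io import MISSING, GenotypeMatrix, TrialTable


@dataclass
class TraitSpec:
    """Variance-component specification for one simulated trait."""

    mu: float = 0.0
    var_gca_line: float = 0.0
    var_gca_tester: float = 0.0
    var_sca: float = 0.0
    var_env: float = 0.0
    var_gxe: float = 0.0
    var_error: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "var_gca_line",
            "var_gca_tester",
            "var_sca",
            "var_env",
            "var_gxe",
            "var_error",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MarkerSpec:
    """Genotype-panel specification.

    ``fst`` controls subpopulation differentiation (Balding-Nichols);
    ``admixture_alpha`` is the symmetric Dirichlet concentration of the
    per-sample ancestry proportions (small = near-pure ancestry);
    ``het_rate`` is the residual fraction of heterozygous draws kept as-is
    (the rest are flipped to a random homozygote, mimicking inbreds).
    """

    n_markers: int = 2000
    k: int = 3
    fst: float = 0.3
    admixture_alpha: float = 0.05
    het_rate: float = 0.05
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0,1)")
        if self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")
        for name in ("het_rate", "missing_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0,1)")


@dataclass
class SimConfig:
    n_lines: int = 60
    n_testers: int = 2
    n_envs: int = 8
    n_reps: int = 2
    traits: dict[str, TraitSpec] = field(
        default_factory=lambda: {"pva": TraitSpec(mu=12.0)}
    )
    #: optional map line_id -> "HGA"/"HGB"; when given, SCA effects are the
    #: planted +-d pattern instead of random draws
    group_structure: dict[str, str] | None = None
    #: each tester's own heterotic group (lines of the opposite group get +d
    #: SCA with it); default T1 in HGA, T2 in HGB
    tester_groups: dict[str, str] | None = None
    marker: MarkerSpec = field(default_factory=MarkerSpec)
    seed: int = 0

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i + 1:03d}" for i in range(self.n_lines)]

    @property
    def tester_ids(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_testers)]


@dataclass
class TruthBundle:
    """Ground truth of one simulation run."""

    gca_line: dict[str, float] | None = None
    gca_tester: dict[str, float] | None = None
    sca: dict[tuple[str, str], float] | None = None
    groups: dict[str, str] | None = None
    q: pd.DataFrame | None = None  # samples x K admixture proportions
    subpop_labels: dict[str, int] | None = None


def _center(arr: np.ndarray) -> np.ndarray:
    """Remove all marginal means so every axis sums to zero exactly."""
    out = arr.astype(float).copy()
    for ax in range(out.ndim):
        out -= out.mean(axis=ax, keepdims=True)
    return out


def default_group_structure(config: SimConfig) -> dict[str, str]:
    """Even HGA/HGB split of the configured lines (first half HGA)."""
    lines = config.line_ids
    half = len(lines) // 2
    return {
        lid: ("HGA" if i < half else "HGB") for i, lid in enumerate(lines)
    }


def simulate_trial(config: SimConfig) -> tuple[TrialTable, TruthBundle]:
    """Simulate a balanced multi-environment line x tester trial.

    Plot value = mu + env + rep(env) + gca_line + gca_tester + sca
    + line x env + tester x env + line x tester x env + error.  Each random
    term is i.i.d. normal with its configured variance, then centered within
    its factor so the GCA/SCA zero-sum constraints hold exactly.  When
    ``group_structure`` is given, sca(line, tester) is +d for lines whose
    group is opposite to the tester's own group and -d otherwise, with
    d = sqrt(var_sca).
    """
    rng = np.random.default_rng([config.seed, 101])
    nl, nt, ne, nr = config.n_lines, config.n_testers, config.n_envs, config.n_reps
    lines, testers = config.line_ids, config.tester_ids
    envs = [f"E{k + 1}" for k in range(ne)]

    li, ti, ei, ri = np.meshgrid(
        np.arange(nl), np.arange(nt), np.arange(ne), np.arange(nr), indexing="ij"
    )
    li, ti, ei, ri = (x.ravel() for x in (li, ti, ei, ri))

    frame = pd.DataFrame(
        {
            "line": np.asarray(lines)[li],
            "tester": np.asarray(testers)[ti],
            "env": np.asarray(envs)[ei],
            "rep": ri + 1,
        }
    )

    tester_groups = config.tester_groups or {
        t: ("HGA" if i % 2 == 0 else "HGB")
        for i, t in enumerate(testers)
    }

    truth = TruthBundle(groups=dict(config.group_structure or {}))
    traits = {}
    for trait, spec in config.traits.items():
        env_eff = _center(rng.normal(0, np.sqrt(spec.var_env), ne))
        rep_eff = np.zeros((ne, nr))  # rep(env) carries no configured variance
        gl = _center(rng.normal(0, np.sqrt(spec.var_gca_line), nl))
        gt = _center(rng.normal(0, np.sqrt(spec.var_gca_tester), nt))
        if config.group_structure is not None:
            d = np.sqrt(spec.var_sca)
            sca = np.empty((nl, nt))
            for a, lid in enumerate(lines):
                for b, tid in enumerate(testers):
                    opposite = config.group_structure[lid] != tester_groups[tid]
                    sca[a, b] = d if opposite else -d
            sca = _center(sca)
        else:
            sca = _center(rng.normal(0, np.sqrt(spec.var_sca), (nl, nt)))
        sd_gxe = np.sqrt(spec.var_gxe)
        lxe = _center(rng.normal(0, sd_gxe, (nl, ne)))
        txe = _center(rng.normal(0, sd_gxe, (nt, ne)))
        lxtxe = _center(rng.normal(0, sd_gxe, (nl, nt, ne)))
        err = rng.normal(0, np.sqrt(spec.var_error), li.shape[0])

        values = (
            spec.mu
            + env_eff[ei]
            + rep_eff[ei, ri]
            + gl[li]
            + gt[ti]
            + sca[li, ti]
            + lxe[li, ei]
            + txe[ti, ei]
            + lxtxe[li, ti, ei]
            + err
        )
        frame[trait] = values
        traits[trait] = spec
        if truth.gca_line is None:
            truth.gca_line = dict(zip(lines, gl))
            truth.gca_tester = dict(zip(testers, gt))
            truth.sca = {
                (lid, tid): sca[a, b]
                for a, lid in enumerate(lines)
                for b, tid in enumerate(testers)
            }

    trial = TrialTable(data=frame, traits=list(config.traits))
    return trial, truth


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, TruthBundle]:
    """Simulate a structured biallelic SNP panel for lines + testers.

    Per marker an ancestral frequency p ~ U(0.05, 0.95) is drawn and K
    subpopulation frequencies follow the Balding-Nichols model
    Beta(p(1-fst)/fst, (1-p)(1-fst)/fst).  Each sample draws admixture
    proportions from a symmetric Dirichlet and genotypes are binomial(2, .)
    draws at the sample's mixed frequency.  Heterozygous draws are flipped to
    a random homozygote with probability 1 - het_rate; entries are then
    masked missing at ``missing_rate``.
    """
    rng = np.random.default_rng([config.seed, 202])
    spec = config.marker
    samples = config.line_ids + config.tester_ids
    n, m, k = len(samples), spec.n_markers, spec.k

    p = rng.uniform(0.05, 0.95, m)
    shape1 = p * (1 - spec.fst) / spec.fst
    shape2 = (1 - p) * (1 - spec.fst) / spec.fst
    freqs = rng.beta(shape1, shape2, size=(k, m))
    q = rng.dirichlet(np.full(k, spec.admixture_alpha), size=n)

    mixed = q @ freqs  # n x m per-sample alt-allele frequency
    geno = rng.binomial(2, mixed).astype(np.int8)

    het = geno == 1
    flip = het & (rng.random((n, m)) > spec.het_rate)
    # flipped hets become a random homozygote
    geno[flip] = np.where(rng.random((n, m))[flip] < 0.5, 0, 2).astype(np.int8)

    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        geno[mask] = MISSING

    markers = pd.DataFrame(
        {
            "marker_id": [f"M{j + 1:05d}" for j in range(m)],
            "chrom": [str(j % 10 + 1) for j in range(m)],
            "pos": [j // 10 + 1 for j in range(m)],
        }
    )
    truth = TruthBundle(
        q=pd.DataFrame(q, index=samples, columns=[f"K{i + 1}" for i in range(k)]),
        subpop_labels={s: int(np.argmax(q[i])) for i, s in enumerate(samples)},
    )
    geno_matrix = GenotypeMatrix(samples=samples, markers=markers, calls=geno)
    return geno_matrix, truth
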