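import numpy as np
import pandas as pd
import pytest

from heterokit.io import GenotypeMatrix, TrialTable
from heterokit.simulate import MarkerSpec, SimConfig, TraitSpec


def make_trial(cross_values, envs=1, reps=1, trait="pva", noise=None, seed=0):
    """Build a balanced TrialTable from a lines x testers array of cross
    means; optional iid noise added per plot."""
    cross_values = np.asarray(cross_values, dtype=float)
    nl, nt = cross_values.shape
    lines = [f"L{i + 1:03d}" for i in range(nl)]
    testers = [f"T{i + 1}" for i in range(nt)]
    rng = np.random.default_rng(seed)
    rows = []
    for li, l in enumerate(lines):
        for ti, t in enumerate(testers):
            for e in range(envs):
                for r in range(reps):
                    val = cross_values[li, ti]
                    if noise is not None:
                        val += rng.normal(0, noise)
                    rows.append(
                        {"line": l, "tester": t, "env": f"E{e + 1}",
                         "rep": r + 1, trait: val}
                    )
    return TrialTable(data=pd.DataFrame(rows), traits=[trait])


def make_genotypes(calls, samples=None, marker_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"S{i + 1}" for i in range(n)]
    marker_ids = marker_ids or [f"M{j + 1}" for j in range(m)]
    markers = pd.DataFrame({"marker_id": marker_ids, "chrom": "1",
                            "pos": range(1, m + 1)})
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


@pytest.fixture
def spec_table_trial():
    """The 3 lines x 2 testers worked example ((10,8),(12,6),(8,10))."""
    return make_trial([[10, 8], [12, 6], [8, 10]])


@pytest.fixture
def small_sim_config():
    return SimConfig(
        n_lines=8,
        n_testers=2,
        n_envs=4,
        n_reps=2,
        traits={"pva": TraitSpec(mu=12.0, var_gca_line=1.0, var_sca=0.5,
                                 var_env=1.0, var_gxe=0.2, var_error=0.5)},
        marker=MarkerSpec(n_markers=120, k=2, fst=0.3, admixture_alpha=0.05,
                          het_rate=0.05, missing_rate=0.02),
        seed=11,
    )
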