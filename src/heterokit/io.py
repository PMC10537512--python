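"""Input/output for trial tables, genotype matrices and dendrograms.

Tabular dialects
----------------
Phenotype CSV: long format, one row per plot, mandatory columns
``line,tester,env,rep`` plus at least one numeric trait column; empty trait
cells are missing values, never zeros.

Genotype matrix CSV: samples in rows, first column sample ids, header row of
marker ids, cells in ``{0,1,2,NA}`` counting copies of the alternate allele.

VCF: v4.x, read-only, ``GT`` field; only biallelic records are imported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # internal code for a missing genotype call

#: default plot area (m^2): 5 m row x 0.75 m row spacing
DEFAULT_PLOT_AREA_M2 = 3.75

REQUIRED_TRIAL_COLUMNS = ("line", "tester", "env", "rep")


class TrialFormatError(ValueError):
    """Raised for malformed phenotype tables."""


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype inputs."""


@dataclass
class TrialTable:
    """Plot-level phenotype records of a line x tester trial.

    ``data`` holds one row per plot with columns ``line``, ``tester``,
    ``env``, ``rep``, optionally ``block``, a boolean ``is_check`` column
    (True for rows where the "line" is itself a tester, e.g. the T1 x T2
    check hybrid), and one numeric column per trait (NaN = missing).
    """

    data: pd.DataFrame
    traits: list[str]

    def __post_init__(self) -> None:
        for col in REQUIRED_TRIAL_COLUMNS:
            if col not in self.data.columns:
                raise TrialFormatError(f"missing mandatory column {col!r}")
        if "is_check" not in self.data.columns:
            testers = set(self.data["tester"])
            self.data = self.data.assign(
                is_check=self.data["line"].isin(testers)
            )
        key_cols = list(REQUIRED_TRIAL_COLUMNS)
        dup = self.data.duplicated(subset=key_cols, keep=False)
        if dup.any():
            first = self.data.loc[dup, key_cols].iloc[0].tolist()
            raise TrialFormatError(
                f"duplicate plot key (line,tester,env,rep)={tuple(first)}"
            )
        non_check = self.data.loc[~self.data["is_check"]]
        overlap = set(non_check["line"]) & set(self.data["tester"])
        if overlap:
            raise TrialFormatError(
                f"line ids also used as tester ids without check flag: {sorted(overlap)}"
            )

    @property
    def lines(self) -> list[str]:
        return sorted(set(self.data.loc[~self.data["is_check"], "line"]))

    @property
    def testers(self) -> list[str]:
        return sorted(set(self.data["tester"]))

    @property
    def envs(self) -> list[str]:
        return sorted(set(self.data["env"].astype(str)))

    @property
    def design(self) -> tuple[int, int, int, int]:
        """(n_lines, n_testers, n_envs, n_reps)."""
        return (
            len(self.lines),
            len(self.testers),
            len(self.envs),
            int(self.data["rep"].nunique()),
        )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for samples x markers.

    ``calls`` is an int8 array of alternate-allele dosages with entries in
    {0, 1, 2, MISSING}.  ``markers`` is a DataFrame with columns
    ``marker_id, chrom, pos`` (1-based positions; 0 = unknown).
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise GenotypeFormatError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.samples[i]!r}, marker {self.marker_ids[j]!r}"
            )
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[
                self.markers["marker_id"].duplicated(), "marker_id"
            ].iloc[0]
            raise GenotypeFormatError(f"duplicate marker id {dup!r}")
        if (self.markers["pos"] < 0).any():
            raise GenotypeFormatError("negative marker position")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to markers where ``keep`` is True,
        preserving order."""
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep].copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            markers=self.markers.copy(),
            calls=self.calls[idx, :].copy(),
        )


def read_trial_csv(path, schema: dict[str, str] | None = None) -> TrialTable:
    """Read a long-format phenotype CSV into a :class:`TrialTable`.

    ``schema`` maps canonical column names (``line``, ``tester``, ``env``,
    ``rep``, ``block``, trait names) to the actual file headers.  Columns not
    covered by the schema and not among the mandatory names are treated as
    trait columns.  Empty trait cells become NaN (missing), never zero.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {v: k for k, v in schema.items()}
        raw = raw.rename(columns=rename)
    for col in REQUIRED_TRIAL_COLUMNS:
        if col not in raw.columns:
            raise TrialFormatError(f"missing mandatory column {col!r} in {path}")
    meta_cols = set(REQUIRED_TRIAL_COLUMNS) | {"block", "is_check"}
    trait_cols = [c for c in raw.columns if c not in meta_cols]
    if not trait_cols:
        raise TrialFormatError(f"no trait columns found in {path}")

    out = raw.copy()
    out["rep"] = pd.to_numeric(out["rep"], errors="raise").astype(int)
    for col in trait_cols:
        cells = out[col].str.strip()
        parsed = pd.to_numeric(cells.replace({"": None, "NA": None}), errors="coerce")
        bad = parsed.isna() & ~cells.isin(("", "NA"))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialFormatError(
                f"non-numeric value {cells.iloc[row]!r} for trait {col!r} "
                f"at data row {row + 1}"
            )
        out[col] = parsed.astype(float)
    if "is_check" in out.columns:
        out["is_check"] = out["is_check"].str.lower().isin(("1", "true", "yes"))
    return TrialTable(data=out.reset_index(drop=True), traits=trait_cols)


def write_trial_csv(trial: TrialTable, path) -> None:
    trial.data.to_csv(path, index=False)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple[str, str, int]] = []
    calls: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        dosages = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            # half-missing diploid calls count as missing
            dosages[i] = MISSING if (a < 0 or b < 0) else a + b
        marker_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        rows.append((marker_id, str(variant.CHROM), int(variant.POS)))
        calls.append(dosages)
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    mat = (
        np.stack(calls, axis=1)
        if calls
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, markers=markers, calls=mat)


def _read_genotypes_csv(path) -> GenotypeMatrix:
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    samples = [str(s) for s in raw.index]
    marker_ids = [str(m) for m in raw.columns]
    calls = np.empty((len(samples), len(marker_ids)), dtype=np.int8)
    for j, m in enumerate(raw.columns):
        col = raw[m].str.strip()
        for i, cell in enumerate(col):
            if cell in ("NA", ""):
                calls[i, j] = MISSING
            elif cell in ("0", "1", "2"):
                calls[i, j] = int(cell)
            else:
                raise GenotypeFormatError(
                    f"unparseable genotype cell {cell!r} at sample "
                    f"{samples[i]!r}, marker {m!r}"
                )
    markers = pd.DataFrame(
        {"marker_id": marker_ids, "chrom": "0", "pos": 0}
    )
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


def read_genotypes(path, dialect: str = "matrix-csv") -> GenotypeMatrix:
    """Read SNP calls from ``vcf`` or ``matrix-csv`` input.

    Diploid GT fields are mapped to alternate-allele dosage; half-missing
    calls map to missing; multi-allelic VCF records are skipped (count
    logged).
    """
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    if dialect == "matrix-csv":
        return _read_genotypes_csv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes_csv(geno: GenotypeMatrix, path) -> None:
    """Write the matrix-csv dialect (samples x markers, NA = missing)."""
    cells = geno.calls.astype(object)
    cells[geno.calls == MISSING] = "NA"
    df = pd.DataFrame(cells, index=geno.samples, columns=geno.marker_ids)
    df.to_csv(path, index_label="sample")


def compute_grain_yield(
    fresh_weight_kg: float,
    moisture_pct: float,
    plot_area_m2: float = DEFAULT_PLOT_AREA_M2,
) -> float:
    """Grain yield (kg/ha) adjusted to 15% moisture.

    yield = fresh_weight x (100 - moisture)/85 x 10000/area.  At exactly 15%
    moisture the adjustment factor is 1.
    """
    if not (math.isfinite(fresh_weight_kg) and math.isfinite(moisture_pct)):
        raise ValueError("non-finite input")
    if not 0 <= moisture_pct < 100:
        raise ValueError(f"moisture_pct {moisture_pct} outside [0, 100)")
    if plot_area_m2 <= 0:
        raise ValueError("plot_area_m2 must be positive")
    return fresh_weight_kg * (100.0 - moisture_pct) / 85.0 * 10000.0 / plot_area_m2


def write_newick(linkage_matrix: np.ndarray | None, leaf_names: list[str]) -> str:
    """Serialize a hierarchical merge tree as a newick string.

    ``linkage_matrix`` is a scipy-style (n-1) x 4 linkage array; branch
    lengths are height differences between parent and child.  A single leaf
    serializes to ``"name;"``.
    """
    n = len(leaf_names)
    if n == 1:
        return f"{leaf_names[0]};"
    if linkage_matrix is None or len(linkage_matrix) != n - 1:
        raise ValueError("linkage matrix inconsistent with leaf count")

    from scipy.cluster.hierarchy import to_tree

    root = to_tree(linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
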