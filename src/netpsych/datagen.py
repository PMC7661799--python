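"""Latent-Gaussian synthetic data for two-group psychometric network studies.

Subject x measure tables are drawn from a zero-mean multivariate normal whose
precision (inverse covariance) matrix is the ground truth: off-diagonal zeros
encode conditional independence, so the generator gives downstream estimators
a known partial-correlation network to recover.  Ordinal measures are produced
by cutting the latent scale at fixed thresholds (the data-generating model
behind the polychoric correlation); continuous measures are an affine map of
the latent score onto the instrument range.

The latent scale is fixed to unit variances (the precision is rescaled to
correlation form before sampling), so thresholds read as standard-normal
quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "VariableSpec",
    "GroupSpec",
    "MeasureTable",
    "discretize_latent",
    "thresholds_from_probs",
    "generate_group_sample",
    "asd_td_specs",
    "ASD_TD_VARIABLE_NAMES",
]


@dataclass(frozen=True)
class VariableSpec:
    """One measure column: its name, typing and instrument range.

    ``levels`` is the number of ordinal categories (``None`` for continuous
    measures); ``bounds`` is the (min, max) of the instrument scale.
    """

    name: str
    kind: str  # "continuous" | "ordinal"
    levels: int | None = None
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == "ordinal":
            if self.levels is None or self.levels < 2:
                raise ValueError(
                    f"ordinal variable {self.name!r} needs levels >= 2, got {self.levels}"
                )
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"variable {self.name!r}: bounds must satisfy min < max")


@dataclass
class GroupSpec:
    """Ground truth for one group: sample size, typing and latent precision.

    ``precision`` is the p x p symmetric positive-definite inverse covariance
    on the latent scale; ``thresholds`` maps each ordinal variable name to its
    ``levels - 1`` strictly increasing standard-normal cut points.
    """

    label: str
    n: int
    variables: list[VariableSpec]
    precision: np.ndarray
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        self.thresholds = {k: np.asarray(v, dtype=float) for k, v in self.thresholds.items()}
        self.validate()

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate variable names in group {self.label!r}")
        p = len(self.variables)
        if self.precision.shape != (p, p):
            raise ValueError(
                f"group {self.label!r}: precision shape {self.precision.shape} "
                f"does not match {p} variables"
            )
        if not np.allclose(self.precision, self.precision.T, atol=1e-10):
            raise ValueError(f"group {self.label!r}: precision matrix is not symmetric")
        eigvals = np.linalg.eigvalsh(self.precision)
        if eigvals.min() <= 0:
            raise ValueError(
                f"group {self.label!r}: precision matrix is not positive definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        for v in self.variables:
            if v.kind != "ordinal":
                continue
            if v.name not in self.thresholds:
                raise ValueError(f"group {self.label!r}: missing thresholds for {v.name!r}")
            t = self.thresholds[v.name]
            if len(t) != v.levels - 1:
                raise ValueError(
                    f"group {self.label!r}: variable {v.name!r} needs {v.levels - 1} "
                    f"thresholds, got {len(t)}"
                )
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"group {self.label!r}: thresholds for {v.name!r} are not strictly increasing"
                )
        if self.n < p + 1:
            warnings.warn(
                f"group {self.label!r}: n={self.n} < p+1={p + 1}; "
                "network estimates will be unstable",
                stacklevel=2,
            )


@dataclass
class MeasureTable:
    """A subjects x measures table with per-row group labels and typing."""

    data: pd.DataFrame  # 'group' column + one column per variable
    variables: list[VariableSpec]

    GROUP_COLUMN = "group"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data[self.GROUP_COLUMN]))

    def values(self) -> np.ndarray:
        return self.data[self.names].to_numpy(dtype=float)

    def select_group(self, label: str) -> "MeasureTable":
        sub = self.data[self.data[self.GROUP_COLUMN] == label].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"no rows with group label {label!r}")
        return MeasureTable(sub, self.variables)

    def validate(self) -> None:
        if self.GROUP_COLUMN not in self.data.columns:
            raise ValueError(f"table is missing the {self.GROUP_COLUMN!r} column")
        for v in self.variables:
            if v.name not in self.data.columns:
                raise ValueError(f"table is missing declared column {v.name!r}")
            col = self.data[v.name].to_numpy()
            if np.any(pd.isna(col)):
                raise ValueError(f"column {v.name!r} contains missing values")
            vals = col.astype(float)
            if v.kind == "ordinal":
                if not np.allclose(vals, np.round(vals)):
                    bad = int(np.flatnonzero(~np.isclose(vals, np.round(vals)))[0])
                    raise ValueError(
                        f"column {v.name!r}, row {bad}: non-integer value in ordinal column"
                    )
                lo, hi = v.bounds
                out = np.flatnonzero((vals < lo) | (vals > hi))
                if out.size:
                    raise ValueError(
                        f"column {v.name!r}, row {int(out[0])}: value {vals[out[0]]} "
                        f"outside declared range [{lo}, {hi}]"
                    )

    @staticmethod
    def concat(tables: list["MeasureTable"]) -> "MeasureTable":
        first = tables[0]
        for t in tables[1:]:
            if t.names != first.names:
                raise ValueError("cannot concatenate tables with different variables")
        data = pd.concat([t.data for t in tables], ignore_index=True)
        return MeasureTable(data, first.variables)


def discretize_latent(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map latent scores to ordinal codes: the count of thresholds strictly below.

    Output values lie in ``{0, ..., len(thresholds)}``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty 1-d array")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(thresholds, np.asarray(values, dtype=float), side="left").astype(int)


def thresholds_from_probs(probs: np.ndarray) -> np.ndarray:
    """Standard-normal cut points reproducing the given category probabilities."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("category probabilities must be positive and sum to 1")
    return ndtri(np.cumsum(probs)[:-1])


def _latent_correlation(precision: np.ndarray) -> np.ndarray:
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def generate_group_sample(spec: GroupSpec, seed: int) -> MeasureTable:
    """Draw one group's subjects x measures table; deterministic given ``seed``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    corr = _latent_correlation(spec.precision)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((spec.n, len(spec.variables))) @ chol.T

    cols: dict[str, np.ndarray] = {MeasureTable.GROUP_COLUMN: np.repeat(spec.label, spec.n)}
    for j, v in enumerate(spec.variables):
        if v.kind == "ordinal":
            lo, _ = v.bounds
            cols[v.name] = discretize_latent(z[:, j], spec.thresholds[v.name]) + int(lo)
        else:
            lo, hi = v.bounds
            center, scale = (lo + hi) / 2.0, (hi - lo) / 6.0
            cols[v.name] = np.round(center + scale * z[:, j], 2)
    return MeasureTable(pd.DataFrame(cols), spec.variables)


# --- the 11-measure two-group study design ---------------------------------

ASD_TD_VARIABLE_NAMES = [
    "B-CST", "E-CST", "I-CST",
    "NPE-ET", "PPE-ET", "NMS-ET", "PMS-ET",
    "E-SIPI", "I-SIPI", "RC-SIPI", "RE-SIPI",
]

# The communicating node communities built into the ASD-like precision:
# a bridged pair of blocks plus one conditionally independent (isolated) node.
ASD_BLOCK_A = ["I-SIPI", "PMS-ET", "NMS-ET", "PPE-ET", "NPE-ET", "RE-SIPI"]
ASD_BLOCK_B = ["E-CST", "B-CST", "I-CST", "RC-SIPI"]
ASD_ISOLATED = "E-SIPI"


def _binom_probs(k: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(k + 1), k, p)


def _default_variables() -> list[VariableSpec]:
    specs = []
    for name in ASD_TD_VARIABLE_NAMES:
        if name.endswith("-CST"):
            specs.append(VariableSpec(name, "ordinal", levels=6, bounds=(0, 5)))
        elif name.endswith("-ET"):
            # two 0-7 accuracy scales summed: integer 0-14
            specs.append(VariableSpec(name, "ordinal", levels=15, bounds=(0, 14)))
        elif name == "E-SIPI" or name == "I-SIPI":
            specs.append(VariableSpec(name, "ordinal", levels=5, bounds=(0, 4)))
        elif name == "RC-SIPI":
            specs.append(VariableSpec(name, "ordinal", levels=9, bounds=(0, 8)))
        else:  # RE-SIPI: 36 response-evaluation items summed, near-continuous
            specs.append(VariableSpec(name, "continuous", bounds=(0, 36)))
    return specs


def _default_thresholds(variables: list[VariableSpec]) -> dict[str, np.ndarray]:
    """Skewed instrument marginals: most children score near the scale top."""
    probs = {
        "B-CST": [0.05, 0.10, 0.15, 0.25, 0.25, 0.20],
        "E-CST": [0.03, 0.05, 0.10, 0.17, 0.30, 0.35],
        "I-CST": [0.04, 0.08, 0.15, 0.25, 0.28, 0.20],
        "E-SIPI": [0.05, 0.08, 0.15, 0.32, 0.40],
        "I-SIPI": [0.10, 0.18, 0.32, 0.28, 0.12],
    }
    out: dict[str, np.ndarray] = {}
    for v in variables:
        if v.kind != "ordinal":
            continue
        if v.name in probs:
            out[v.name] = thresholds_from_probs(np.asarray(probs[v.name]))
        elif v.name.endswith("-ET"):
            out[v.name] = thresholds_from_probs(_binom_probs(14, 0.78))
        else:  # RC-SIPI: roughly centered
            out[v.name] = thresholds_from_probs(_binom_probs(8, 0.45))
    return out


def _exchangeable_precision(p: int, partial: float) -> np.ndarray:
    if not partial < 1.0 / (p - 1):
        raise ValueError(f"uniform partial correlation {partial} infeasible at p={p}")
    k = np.full((p, p), -partial)
    np.fill_diagonal(k, 1.0)
    return k


def asd_td_specs(
    n_td: int = 81,
    n_asd: int = 76,
    td_partial: float = 0.09,
    within_block: float = 0.3,
    bridge: float = 0.1,
) -> tuple[GroupSpec, GroupSpec]:
    """Ground-truth specs emulating the two-group study structure.

    The TD-like group is a single densely connected component: every pair of
    measures has a positive partial correlation (``td_partial``, the largest
    uniform value feasible at p=11 is just under 0.1).  The ASD-like group has
    three communities: a 6-node block (interpretation / eye-gaze / response
    evaluation), a 4-node block (theory-of-mind subscales + response
    construction), two weak bridge edges between them, and one measure
    (encoding) conditionally independent of everything else.
    """
    variables = _default_variables()
    thresholds = _default_thresholds(variables)
    names = [v.name for v in variables]
    p = len(names)

    prec_td = _exchangeable_precision(p, td_partial)

    prec_asd = np.eye(p)
    idx = {name: i for i, name in enumerate(names)}

    def set_partial(a: str, b: str, value: float) -> None:
        prec_asd[idx[a], idx[b]] = prec_asd[idx[b], idx[a]] = -value

    # 6-node block: ring at `within_block` plus second-neighbour chords at
    # half that (a complete 6-block at 0.3 would not be positive definite).
    ring = ASD_BLOCK_A
    for i, name in enumerate(ring):
        set_partial(name, ring[(i + 1) % len(ring)], within_block)
        set_partial(name, ring[(i + 2) % len(ring)], within_block / 2.0)
    # 4-node block: complete at `within_block`
    for i, a in enumerate(ASD_BLOCK_B):
        for b in ASD_BLOCK_B[i + 1:]:
            set_partial(a, b, within_block)
    # weak bridges between the blocks; E-SIPI stays fully disconnected
    set_partial("PMS-ET", "E-CST", bridge)
    set_partial("RE-SIPI", "RC-SIPI", bridge)

    td = GroupSpec("TD", n_td, variables, prec_td, thresholds)
    asd = GroupSpec("ASD", n_asd, variables, prec_asd, thresholds)
    return td, asd
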