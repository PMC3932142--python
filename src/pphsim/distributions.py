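"""Assumption distributions for the coverage scenarios.

Every model input is an expert-elicited distribution on the percent scale:
either a triangular distribution ``Tri(minimum, likeliest, maximum)`` or a
"uniform" set level, which in the packaged assumption table is always
degenerate (minimum == maximum) and therefore a point mass.  Values are kept
on the percent scale exactly as elicited, so that assumption files round-trip
unchanged; conversion to fractions happens inside the cohort model.

Closed-form moments are provided as oracles for the Monte Carlo engine:
for ``Tri(a, m, b)`` the mean is ``(a + m + b) / 3`` and the variance
``(a^2 + m^2 + b^2 - am - ab - mb) / 18``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "AssumptionError",
    "TriangleSpec",
    "sample_triangle",
    "triangle_mean",
    "triangle_variance",
    "load_assumption_table",
    "spec_from_row",
    "write_assumption_table",
]

_FAMILIES = ("triangle", "uniform")


class AssumptionError(ValueError):
    """Raised when an assumption row is malformed (bad ordering or range)."""


@dataclass(frozen=True)
class TriangleSpec:
    """One assumption distribution on the percent scale.

    Parameters
    ----------
    minimum, mode, maximum
        Support bounds and likeliest value, in percent (0-100), with
        ``minimum <= mode <= maximum``.
    family
        ``"triangle"`` (default) or ``"uniform"``.  A spec with
        ``minimum == maximum`` degenerates to a point mass in either family.
    label
        Optional assumption identifier, used in error messages.
    """

    minimum: float
    mode: float
    maximum: float
    family: str = "triangle"
    label: str | None = None

    def __post_init__(self) -> None:
        name = self.label or "assumption"
        if self.family not in _FAMILIES:
            raise AssumptionError(
                f"{name}: unknown distribution family {self.family!r}"
            )
        if not (self.minimum <= self.mode <= self.maximum):
            raise AssumptionError(
                f"{name}: requires minimum <= likeliest <= maximum, got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )
        if self.minimum < 0 or self.maximum > 100:
            raise AssumptionError(
                f"{name}: percent values must lie in [0, 100], got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def is_point_mass(self) -> bool:
        return self.minimum == self.maximum

    def mean(self) -> float:
        """Exact mean, in percent."""
        if self.family == "uniform":
            return (self.minimum + self.maximum) / 2.0
        return (self.minimum + self.mode + self.maximum) / 3.0

    def variance(self) -> float:
        """Exact variance, in percent squared; 0 for a point mass."""
        a, m, b = self.minimum, self.mode, self.maximum
        if self.family == "uniform":
            return (b - a) ** 2 / 12.0
        return (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values via inverse-CDF transform of uniform variates.

        A point mass returns ``n`` copies of the single value without
        consuming randomness; all draws lie within the support exactly.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.is_point_mass:
            return np.full(n, float(self.mode))
        if self.family == "uniform":
            return rng.uniform(self.minimum, self.maximum, size=n)
        return rng.triangular(self.minimum, self.mode, self.maximum, size=n)


def sample_triangle(spec: TriangleSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    return spec.sample(n, rng)


def triangle_mean(spec: TriangleSpec) -> float:
    return spec.mean()


def triangle_variance(spec: TriangleSpec) -> float:
    return spec.variance()


_TABLE_COLUMNS = [
    "assumption_id",
    "scenario",
    "minimum",
    "likeliest",
    "maximum",
    "distribution",
    "source",
]


def _default_table_path() -> Path:
    return Path(__file__).parent / "data" / "table1_assumptions.csv"


def spec_from_row(row: pd.Series) -> TriangleSpec:
    """Build a :class:`TriangleSpec` from one assumption-table row."""
    return TriangleSpec(
        minimum=float(row["minimum"]),
        mode=float(row["likeliest"]),
        maximum=float(row["maximum"]),
        family=str(row["distribution"]).lower(),
        label=f"{row['assumption_id']}[{row['scenario']}]",
    )


def load_assumption_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load an assumption table (the packaged default reproduces the
    published elicitation table verbatim) and validate every row."""
    df = pd.read_csv(path if path is not None else _default_table_path())
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AssumptionError(f"assumption table missing columns: {missing}")
    for _, row in df.iterrows():
        spec_from_row(row)  # raises AssumptionError naming the row
    return df


def write_assumption_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=_TABLE_COLUMNS)


def specs_by_id(df: pd.DataFrame, scenario: str | None = None) -> dict[str, TriangleSpec]:
    """Map assumption_id -> spec for one scenario block (or the shared block
    when ``scenario`` is None)."""
    block = df[df["scenario"] == (scenario or "all")]
    return {str(r["assumption_id"]): spec_from_row(r) for _, r in block.iterrows()}
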