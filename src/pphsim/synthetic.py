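"""Synthetic delivery cohorts and verbal-autopsy style death tabulation.

Unlike the cohort model — which propagates assumption uncertainty through
expectations — this module emulates data *collection*: every woman's path
through CDK receipt, misoprostol use, PPH and death is an individual
Bernoulli draw, plus a small competing hazard of death from non-PPH causes
so the death table has the full cause mix.  The generator's defaults are the
field project's observed proportions (69% CDK receipt, 94% misoprostol use
among receivers, 68% blood-mat use, PPH incidence 11.5%/17% with/without
misoprostol, 0.3% death given PPH).

The module also carries a deterministic reconstruction of the project's 117
maternal deaths from the published per-cause marginal counts (cause, timing
of death, misoprostol use, place of delivery, attendant).  Joint attribute
distributions were never published, so the reconstruction assigns attributes
independently within cause, padding with "unknown" where the printed
marginals fall short of the cause total; it is a synthetic stand-in whose
marginals — and therefore every published percentage — are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CAUSES",
    "DIRECT_CAUSES",
    "GeneratorParams",
    "generate_cohort",
    "tabulate_deaths",
    "DeathTabulation",
    "recover_parameters",
    "RecoveredParams",
    "reference_death_records",
    "load_reference_deaths",
]

CAUSES = (
    "pph",
    "aph",
    "eclampsia",
    "obstructed_labor",
    "ruptured_uterus",
    "other_direct",
    "indirect",
)
DIRECT_CAUSES = CAUSES[:-1]

TIMINGS = ("before", "during", "after")
PLACES = ("home", "facility")
ATTENDANTS = ("skilled", "unskilled")

# Published per-cause marginal counts of the 117 verbal-autopsy deaths:
# total, timing (before/during/after), number who took misoprostol,
# place (home/facility), attendant (skilled/unskilled).  Shortfalls against
# the cause total are unknowns.
_REFERENCE_COUNTS: dict[str, dict] = {
    "pph": {"n": 54, "timing": (4, 7, 42), "miso": 17, "place": (34, 15), "attendant": (19, 31)},
    "aph": {"n": 5, "timing": (1, 3, 1), "miso": 1, "place": (0, 2), "attendant": (1, 4)},
    "eclampsia": {"n": 27, "timing": (11, 3, 13), "miso": 3, "place": (4, 12), "attendant": (11, 14)},
    "obstructed_labor": {"n": 2, "timing": (0, 2, 0), "miso": 0, "place": (0, 0), "attendant": (0, 2)},
    "ruptured_uterus": {"n": 2, "timing": (1, 0, 1), "miso": 1, "place": (1, 0), "attendant": (0, 2)},
    "other_direct": {"n": 20, "timing": (7, 2, 10), "miso": 5, "place": (5, 5), "attendant": (6, 14)},
    "indirect": {"n": 7, "timing": (3, 0, 4), "miso": 0, "place": (3, 1), "attendant": (1, 6)},
}
# Among the 54 PPH deaths, misoprostol use was 17 yes / 16 no / 1 unknown.
_PPH_MISO_NO = 16

_DEATH_COLUMNS = ["woman_id", "cause_of_death", "timing", "took_misoprostol", "place", "attendant"]


def _fill(levels: Sequence[str], counts: Sequence[int], total: int) -> list[str]:
    out: list[str] = []
    for level, k in zip(levels, counts):
        out.extend([level] * k)
    out.extend(["unknown"] * (total - len(out)))
    return out


def reference_death_records() -> pd.DataFrame:
    """Deterministically rebuild the 117 reference death records.

    One row per death with cause, timing, misoprostol use, place and
    attendant; attributes are assigned blockwise within cause so that every
    published marginal count is matched exactly (synthetic reconstruction —
    the true joint distribution was not published).
    """
    rows = []
    wid = 0
    for cause in CAUSES:
        c = _REFERENCE_COUNTS[cause]
        n = c["n"]
        timing = _fill(TIMINGS, c["timing"], n)
        if cause == "pph":
            miso = _fill(("yes", "no"), (c["miso"], _PPH_MISO_NO), n)
        else:
            miso = _fill(("yes",), (c["miso"],), n)
            miso = ["no" if m == "unknown" else m for m in miso]
        place = _fill(PLACES, c["place"], n)
        att = _fill(ATTENDANTS, c["attendant"], n)
        for i in range(n):
            wid += 1
            rows.append((wid, cause, timing[i], miso[i], place[i], att[i]))
    return pd.DataFrame(rows, columns=_DEATH_COLUMNS)


def load_reference_deaths(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged per-death reference CSV."""
    if path is None:
        path = Path(__file__).parent / "data" / "table2_deaths.csv"
    return pd.read_csv(path)


def _attribute_weights_from_reference() -> dict[str, dict[str, tuple]]:
    """Per-cause categorical weights for death attributes, from the reference
    counts with unknowns dropped (falling back to the overall margins when a
    cause has no known values)."""
    totals = {
        "timing": np.array([sum(c["timing"][i] for c in _REFERENCE_COUNTS.values()) for i in range(3)], float),
        "place": np.array([sum(c["place"][i] for c in _REFERENCE_COUNTS.values()) for i in range(2)], float),
        "attendant": np.array([sum(c["attendant"][i] for c in _REFERENCE_COUNTS.values()) for i in range(2)], float),
    }
    out: dict[str, dict[str, tuple]] = {}
    for cause, c in _REFERENCE_COUNTS.items():
        w: dict[str, tuple] = {}
        for attr, levels in (("timing", TIMINGS), ("place", PLACES), ("attendant", ATTENDANTS)):
            counts = np.asarray(c[attr], dtype=float)
            if counts.sum() == 0:
                counts = totals[attr]
            w[attr] = tuple(counts / counts.sum())
        out[cause] = w
    return out


DEFAULT_ATTRIBUTE_WEIGHTS = _attribute_weights_from_reference()

#: Non-PPH cause mix among the 63 non-PPH reference deaths.
DEFAULT_CAUSE_WEIGHTS = {
    cause: _REFERENCE_COUNTS[cause]["n"] / 63.0 for cause in CAUSES if cause != "pph"
}


@dataclass(frozen=True)
class GeneratorParams:
    """Branch probabilities (fractions) for the synthetic cohort.

    ``p_die_other`` is the marginal hazard of a non-PPH maternal death
    (default 63 deaths / 75,000 live births); ``cause_weights`` is the cause
    mix of those deaths.  ``include_unknown_misoprostol_case`` injects one
    PPH death with missing misoprostol status, mirroring the project's one
    excluded case, to exercise missing-data handling in tabulation.
    """

    n_deliveries: int = 100_000
    p_cdk: float = 0.69
    p_use_given_cdk: float = 0.94
    p_mat: float = 0.68
    p_pph_user: float = 0.115
    p_pph_nonuser: float = 0.17
    p_die_given_pph: float = 0.003
    p_die_other: float = 63.0 / 75_000.0
    p_skilled_attendant: float = 0.043
    cause_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_WEIGHTS)
    )
    attribute_weights: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ATTRIBUTE_WEIGHTS.items()}
    )
    include_unknown_misoprostol_case: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_deliveries < 1:
            raise ValueError("n_deliveries must be >= 1")
        for name in (
            "p_cdk", "p_use_given_cdk", "p_mat", "p_pph_user",
            "p_pph_nonuser", "p_die_given_pph", "p_die_other",
            "p_skilled_attendant",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        w = np.array(list(self.cause_weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("cause_weights must be non-negative and sum to 1")
        unknown = set(self.cause_weights) - set(CAUSES)
        if unknown:
            raise ValueError(f"unknown causes in cause_weights: {sorted(unknown)}")

    def with_seed(self, seed: int | None) -> "GeneratorParams":
        return replace(self, seed=seed)


def generate_cohort(params: GeneratorParams) -> pd.DataFrame:
    """Draw one synthetic cohort of home deliveries, one row per woman.

    Deterministic given ``params.seed``.  Logical invariants hold for every
    record: misoprostol use implies CDK receipt, cause/timing are set iff the
    woman died, and a PPH-attributed death implies recorded PPH.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_deliveries

    received = rng.random(n) < params.p_cdk
    used = received & (rng.random(n) < params.p_use_given_cdk)
    mat = rng.random(n) < params.p_mat
    p_pph = np.where(used, params.p_pph_user, params.p_pph_nonuser)
    had_pph = rng.random(n) < p_pph
    died_pph = had_pph & (rng.random(n) < params.p_die_given_pph)
    died_other = ~died_pph & (rng.random(n) < params.p_die_other)
    died = died_pph | died_other

    cause = np.full(n, "", dtype=object)
    cause[died_pph] = "pph"
    n_other = int(died_other.sum())
    if n_other:
        labels = list(params.cause_weights)
        probs = np.array([params.cause_weights[c] for c in labels], dtype=float)
        cause[died_other] = rng.choice(labels, size=n_other, p=probs)

    timing = np.full(n, "", dtype=object)
    place = np.full(n, "home", dtype=object)
    attendant = np.where(
        rng.random(n) < params.p_skilled_attendant, "skilled", "unskilled"
    ).astype(object)
    for c in CAUSES:
        idx = np.flatnonzero(cause == c)
        if idx.size == 0:
            continue
        w = params.attribute_weights[c]
        timing[idx] = rng.choice(TIMINGS, size=idx.size, p=np.asarray(w["timing"]))
        place[idx] = rng.choice(PLACES, size=idx.size, p=np.asarray(w["place"]))
        attendant[idx] = rng.choice(ATTENDANTS, size=idx.size, p=np.asarray(w["attendant"]))

    records = pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1),
            "received_cdk": received,
            "used_misoprostol": pd.array(used, dtype="boolean"),
            "used_mat": mat,
            "had_pph": had_pph,
            "died": died,
            "cause_of_death": cause,
            "timing": timing,
            "place": place,
            "attendant": attendant,
        }
    )
    if params.include_unknown_misoprostol_case:
        pph_deaths = records.index[records["cause_of_death"] == "pph"]
        if len(pph_deaths):
            records.loc[pph_deaths[0], "used_misoprostol"] = pd.NA
    return records


@dataclass(frozen=True)
class DeathTabulation:
    """Cross-tabulation of maternal deaths by cause and attributes."""

    by_cause: pd.DataFrame  # index: cause; columns: deaths, pct
    crosstabs: dict[str, pd.DataFrame]
    n_deaths: int

    @property
    def pph_share_pct(self) -> float:
        return float(self.by_cause.loc["pph", "pct"])

    @property
    def direct_share_pct(self) -> float:
        return round(
            float(self.by_cause.loc[list(DIRECT_CAUSES), "deaths"].sum())
            / self.n_deaths * 100.0,
            1,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: cause counts/shares plus every attribute breakdown."""
        out = self.by_cause.copy()
        for attr, tab in self.crosstabs.items():
            out = out.join(tab.add_prefix(f"{attr}_"))
        return out.fillna(0)


def _death_frame(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no records to tabulate")
    deaths = records.loc[records["died"]].copy()
    if "took_misoprostol" not in deaths.columns:
        miso = deaths["used_misoprostol"]
        deaths["took_misoprostol"] = np.where(
            miso.isna(), "unknown", np.where(miso.fillna(False), "yes", "no")
        )
    return deaths


def tabulate_deaths(records: pd.DataFrame) -> DeathTabulation:
    """Tabulate maternal deaths by cause, with timing / misoprostol / place /
    attendant breakdowns.

    Accepts either generated cohorts (with a ``died`` flag) or per-death
    tables such as the packaged reference file (every row a death).
    Percent shares are reported to 1 d.p.; totals are exact.
    """
    if "died" not in records.columns:
        records = records.assign(died=True)
    deaths = _death_frame(records)
    n = len(deaths)
    if n == 0:
        raise ValueError("no deaths to tabulate")
    cause = pd.Series(
        pd.Categorical(deaths["cause_of_death"], categories=CAUSES),
        index=deaths.index,
        name="cause",
    )
    counts = cause.value_counts(sort=False).reindex(CAUSES, fill_value=0)
    by_cause = pd.DataFrame(
        {"deaths": counts, "pct": (counts / n * 100.0).round(1)}
    )
    by_cause.index.name = "cause"
    crosstabs = {
        attr: pd.crosstab(cause, deaths[attr]).reindex(CAUSES, fill_value=0)
        for attr in ("timing", "took_misoprostol", "place", "attendant")
    }
    return DeathTabulation(by_cause=by_cause, crosstabs=crosstabs, n_deaths=n)


@dataclass(frozen=True)
class RecoveredParams:
    """Empirical branch fractions from a cohort; NaN flags an empty stratum."""

    p_cdk: float
    p_use_given_cdk: float
    p_mat: float
    p_pph_user: float
    p_pph_nonuser: float
    p_die_given_pph: float

    def to_dict(self) -> dict[str, float]:
        return {
            "p_cdk": self.p_cdk,
            "p_use_given_cdk": self.p_use_given_cdk,
            "p_mat": self.p_mat,
            "p_pph_user": self.p_pph_user,
            "p_pph_nonuser": self.p_pph_nonuser,
            "p_die_given_pph": self.p_die_given_pph,
        }


def _frac(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def recover_parameters(records: pd.DataFrame) -> RecoveredParams:
    """Point-estimate the generator's branch probabilities from a cohort."""
    if len(records) == 0:
        raise ValueError("no records")
    used = records["used_misoprostol"].fillna(False).to_numpy(dtype=bool)
    received = records["received_cdk"].to_numpy(dtype=bool)
    had_pph = records["had_pph"].to_numpy(dtype=bool)
    pph_death = (records["cause_of_death"] == "pph").to_numpy(dtype=bool)
    n = len(records)
    return RecoveredParams(
        p_cdk=_frac(int(received.sum()), n),
        p_use_given_cdk=_frac(int(used.sum()), int(received.sum())),
        p_mat=_frac(int(records["used_mat"].sum()), n),
        p_pph_user=_frac(int((had_pph & used).sum()), int(used.sum())),
        p_pph_nonuser=_frac(int((had_pph & ~used).sum()), int((~used).sum())),
        p_die_given_pph=_frac(int(pph_death.sum()), int(had_pph.sum())),
    )
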