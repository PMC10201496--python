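"""Synthetic phosphide-poisoning cohort reconstructed from published contingency tables.

The study population is 2518 patients admitted with acute aluminum-phosphide
(AlP) or zinc-phosphide (ZnP) poisoning, of whom 682 died. The published
record of that cohort consists of two-way contingency tables: each predictor
(age group, sex, cholinesterase level, silver-nitrate test, mode of
poisoning) crossed once with the outcome (recovered/died) and once with the
poison type (AlP/ZnP), plus the poison-by-outcome joint. No patient-level
data are available.

This module rebuilds a patient-level cohort whose crosstabs reproduce every
published cell exactly. For each predictor X the three-way table
X x poison x outcome is completed by iterative proportional fitting (raking)
against the three published two-way margins — the maximum-entropy table
consistent with everything printed — followed by an integer reconciliation
that makes all three margins exact. Predictors are then combined as
conditionally independent given (poison_type, outcome), which is again the
maximum-entropy completion: the published tables carry no information about
predictor-predictor association beyond what poison and outcome induce.

Clinical-examination variables (blood pressure, pulse, echocardiography)
are degenerate in the source tables — abnormal in 100% of deaths and 0% of
survivors — and are generated to satisfy that identity; they are never used
as model features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "AGE_BOUNDS",
    "COHORT_COLUMNS",
    "ContingencySpec",
    "ThreeWayTable",
    "PatientRecord",
    "RakingError",
    "load_printed_margins",
    "rake_three_way",
    "sample_cohort",
    "encode_features",
    "plant_signal",
    "write_cohort_csv",
    "read_cohort_csv",
    "validate_cohort",
]

AGE_GROUPS = ["<10", "10-20", "20-30", "30-40", "40-50", ">50"]

# Published group labels overlap ("<10", ">10-20", ...); groups are taken as
# half-open [lo, hi) except the last, and overall age spans 1-60 years.
AGE_BOUNDS = {
    "<10": (1, 9),
    "10-20": (10, 19),
    "20-30": (20, 29),
    "30-40": (30, 39),
    "40-50": (40, 49),
    ">50": (51, 60),
}

OUTCOME_LEVELS = ["recovered", "died"]
POISON_LEVELS = ["AlP", "ZnP"]

PREDICTOR_LEVELS = {
    "age_group": AGE_GROUPS,
    "sex": ["male", "female"],
    "cholinesterase": ["normal", "abnormal"],
    "silver_nitrate": ["negative", "positive"],
    "mode": ["accidental", "suicidal"],
}

#: Columns of a cohort table, in canonical CSV order.
COHORT_COLUMNS = [
    "age_years",
    "age_group",
    "sex",
    "poison_type",
    "silver_nitrate",
    "cholinesterase",
    "mode",
    "blood_pressure",
    "pulse",
    "echo",
    "outcome",
]

#: Feature order used by :func:`encode_features`.
FEATURE_ORDER = ["age", "sex", "poison_type", "silver_nitrate", "cholinesterase", "mode"]

# Binary codings for the feature matrix (value mapped to 1; the other level to 0).
POSITIVE_CODES = {
    "sex": "male",
    "poison_type": "AlP",
    "silver_nitrate": "positive",
    "cholinesterase": "abnormal",
    "mode": "suicidal",
}


class RakingError(RuntimeError):
    """Iterative proportional fitting failed to converge."""

    def __init__(self, message: str, margin_error: float):
        super().__init__(message)
        self.margin_error = margin_error


@dataclass(frozen=True)
class PatientRecord:
    """One admitted case: six predictors, clinical flags, outcome."""

    age_years: int
    age_group: str
    sex: str
    poison_type: str
    silver_nitrate: str
    cholinesterase: str
    mode: str
    blood_pressure: str
    pulse: str
    echo: str
    outcome: str
    residence: str | None = None
    occupation: str | None = None

    def validate(self) -> None:
        lo, hi = AGE_BOUNDS[self.age_group]
        if not lo <= self.age_years <= hi:
            raise ValueError(
                f"age_years={self.age_years} outside bounds {lo}-{hi} of group {self.age_group!r}"
            )
        for name in ("sex", "cholinesterase", "silver_nitrate", "mode"):
            if getattr(self, name) not in PREDICTOR_LEVELS[name]:
                raise ValueError(f"unknown {name} value {getattr(self, name)!r}")
        if self.poison_type not in POISON_LEVELS:
            raise ValueError(f"unknown poison_type {self.poison_type!r}")
        if self.outcome not in OUTCOME_LEVELS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        expected = "abnormal" if self.outcome == "died" else "normal"
        for name in ("blood_pressure", "pulse", "echo"):
            if getattr(self, name) != expected:
                raise ValueError(
                    f"{name}={getattr(self, name)!r} inconsistent with outcome {self.outcome!r}"
                )


@dataclass(frozen=True)
class ContingencySpec:
    """Published two-way margins of the cohort.

    ``margins_xo[name]`` is the predictor-by-outcome count table and
    ``margins_xp[name]`` the predictor-by-poison table; ``poison_outcome``
    is the poison-by-outcome joint. All tables are DataFrames whose index
    holds the predictor levels.
    """

    total: int
    poison_outcome: pd.DataFrame
    margins_xo: dict[str, pd.DataFrame]
    margins_xp: dict[str, pd.DataFrame]
    rural_count: int
    student_count: int

    def validate(self) -> None:
        if int(self.poison_outcome.values.sum()) != self.total:
            raise ValueError("poison_outcome does not sum to total")
        for name, table in {**self.margins_xo, **self.margins_xp}.items():
            if int(table.values.sum()) != self.total:
                raise ValueError(f"margin {name!r} does not sum to total")


@dataclass(frozen=True)
class ThreeWayTable:
    """Predictor x poison x outcome table raked to the published margins.

    ``raked`` holds the non-negative real IPF fixed point, ``counts`` the
    integer table after reconciliation; both are indexed
    (level, poison, outcome) in the orders given by the level attributes.
    """

    predictor: str
    levels: list[str]
    poison_levels: list[str]
    outcome_levels: list[str]
    raked: np.ndarray
    counts: np.ndarray | None
    margin_error: float

    def collapse(self, axis: str) -> np.ndarray:
        """Sum the integer table over ``axis`` in {'predictor','poison','outcome'}."""
        if self.counts is None:
            raise ValueError("no integer table: margins were not integer counts")
        ax = {"predictor": 0, "poison": 1, "outcome": 2}[axis]
        return self.counts.sum(axis=ax)


def load_printed_margins() -> ContingencySpec:
    """Return the published contingency tables of the 2518-patient cohort.

    Counts are embedded constants; every predictor margin and the
    poison-by-outcome joint sums to the admission total of 2518
    (1836 recovered / 682 died; 1330 AlP / 1188 ZnP).
    """

    def df(rows, index, columns):
        return pd.DataFrame(np.asarray(rows, dtype=int), index=index, columns=columns)

    poison_outcome = df([[708, 622], [1128, 60]], POISON_LEVELS, OUTCOME_LEVELS)

    margins_xo = {
        "age_group": df(
            [[389, 116], [904, 289], [259, 55], [156, 89], [75, 58], [53, 75]],
            AGE_GROUPS,
            OUTCOME_LEVELS,
        ),
        "sex": df([[685, 331], [1151, 351]], ["male", "female"], OUTCOME_LEVELS),
        "cholinesterase": df([[1179, 375], [657, 307]], ["normal", "abnormal"], OUTCOME_LEVELS),
        "silver_nitrate": df([[1145, 129], [691, 553]], ["negative", "positive"], OUTCOME_LEVELS),
        "mode": df([[414, 125], [1422, 557]], ["accidental", "suicidal"], OUTCOME_LEVELS),
    }
    margins_xp = {
        "age_group": df(
            [[252, 253], [588, 605], [156, 158], [150, 95], [87, 46], [97, 31]],
            AGE_GROUPS,
            POISON_LEVELS,
        ),
        "sex": df([[588, 428], [742, 760]], ["male", "female"], POISON_LEVELS),
        "cholinesterase": df([[395, 1159], [935, 29]], ["normal", "abnormal"], POISON_LEVELS),
        "silver_nitrate": df([[92, 1182], [1238, 6]], ["negative", "positive"], POISON_LEVELS),
        "mode": df([[273, 266], [1057, 922]], ["accidental", "suicidal"], POISON_LEVELS),
    }

    spec = ContingencySpec(
        total=2518,
        poison_outcome=poison_outcome,
        margins_xo=margins_xo,
        margins_xp=margins_xp,
        rural_count=2229,
        student_count=1324,
    )
    spec.validate()
    return spec


def _margin_error(t: np.ndarray, m_xo: np.ndarray, m_xp: np.ndarray, joint: np.ndarray) -> float:
    return max(
        np.abs(t.sum(axis=1) - m_xo).max(),
        np.abs(t.sum(axis=2) - m_xp).max(),
        np.abs(t.sum(axis=0) - joint).max(),
    )


def rake_three_way(
    margin_xo: pd.DataFrame,
    margin_xp: pd.DataFrame,
    joint_po: pd.DataFrame,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    predictor: str = "",
) -> ThreeWayTable:
    """Complete a predictor x poison x outcome table from its two-way margins.

    Starting from the independence seed (predictor distribution times the
    poison-outcome joint), iterative proportional fitting cycles over the
    three two-way margins until the largest absolute margin error falls
    below ``tol``. The fixed point is then rounded to integers by choosing,
    per predictor level, the single free cell (AlP-died) inside its
    feasibility box via largest-remainder allocation, which reconciles all
    three margins exactly.
    """
    if not (margin_xo.index.equals(margin_xp.index)):
        raise ValueError("margin_xo and margin_xp must share predictor levels")
    m_xo = margin_xo.to_numpy(dtype=float)
    m_xp = margin_xp.to_numpy(dtype=float)
    joint = joint_po.to_numpy(dtype=float)
    if not np.isclose(m_xo.sum(), m_xp.sum()) or not np.isclose(m_xo.sum(), joint.sum()):
        raise ValueError(
            f"incompatible margins: totals {m_xo.sum()}, {m_xp.sum()}, {joint.sum()} differ"
        )
    if (joint <= 0).any():
        raise ValueError("joint_po must be strictly positive")

    total = joint.sum()
    levels = list(margin_xo.index)
    px = m_xo.sum(axis=1) / total
    t = px[:, None, None] * joint[None, :, :]

    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            s = t.sum(axis=1, keepdims=True)
            t = np.where(s > 0, t * (m_xo[:, None, :] / s), 0.0)
            s = t.sum(axis=2, keepdims=True)
            t = np.where(s > 0, t * (m_xp[:, :, None] / s), 0.0)
            s = t.sum(axis=0, keepdims=True)
            t = np.where(s > 0, t * (joint[None, :, :] / s), 0.0)
            err = _margin_error(t, m_xo, m_xp, joint)
            if err < tol:
                break
        else:
            raise RakingError(
                f"raking did not converge in {max_iter} iterations (margin error {err:.3e})",
                margin_error=err,
            )

    # integer reconciliation only applies when the margins are genuine counts
    integral = all(
        np.allclose(m, np.rint(m), atol=1e-9) for m in (m_xo, m_xp, joint)
    )
    counts = _reconcile_integer(t, m_xo, m_xp, joint) if integral else None
    return ThreeWayTable(
        predictor=predictor,
        levels=levels,
        poison_levels=list(joint_po.index),
        outcome_levels=list(joint_po.columns),
        raked=t,
        counts=counts,
        margin_error=err,
    )


def _reconcile_integer(
    t: np.ndarray, m_xo: np.ndarray, m_xp: np.ndarray, joint: np.ndarray
) -> np.ndarray:
    """Round a raked L x 2 x 2 table so every two-way margin is exact.

    With binary poison and outcome the table has one degree of freedom per
    predictor level once the margins are fixed: the (AlP, died) cell d(l).
    Each d(l) is floored into its feasibility interval and the remaining
    mass up to the global AlP-died total is assigned by largest remainder.
    """
    if t.shape[1] != 2 or t.shape[2] != 2:
        raise NotImplementedError("integer reconciliation requires binary poison and outcome")
    m_xo_i = np.rint(m_xo).astype(int)
    m_xp_i = np.rint(m_xp).astype(int)
    joint_i = np.rint(joint).astype(int)

    d = t[:, 0, 1]
    lo = np.maximum.reduce(
        [np.zeros_like(m_xo_i[:, 1]), m_xo_i[:, 1] - m_xp_i[:, 1], m_xp_i[:, 0] - m_xo_i[:, 0]]
    )
    hi = np.minimum(m_xo_i[:, 1], m_xp_i[:, 0])
    base = np.clip(np.floor(d).astype(int), lo, hi)
    remaining = joint_i[0, 1] - base.sum()
    frac = d - np.floor(d)
    if remaining > 0:
        for idx in np.argsort(-frac, kind="stable"):
            if remaining == 0:
                break
            room = hi[idx] - base[idx]
            add = min(room, remaining)
            base[idx] += add
            remaining -= add
    elif remaining < 0:
        for idx in np.argsort(frac, kind="stable"):
            if remaining == 0:
                break
            room = base[idx] - lo[idx]
            sub = min(room, -remaining)
            base[idx] -= sub
            remaining += sub
    if remaining != 0:
        raise RakingError("integer reconciliation infeasible", margin_error=abs(remaining))

    counts = np.zeros(t.shape, dtype=int)
    counts[:, 0, 1] = base
    counts[:, 0, 0] = m_xp_i[:, 0] - base
    counts[:, 1, 1] = m_xo_i[:, 1] - base
    counts[:, 1, 0] = m_xo_i[:, 0] - m_xp_i[:, 0] + base
    if (counts < 0).any():
        raise RakingError("integer reconciliation produced negative cells", margin_error=np.inf)
    assert (counts.sum(axis=1) == m_xo_i).all()
    assert (counts.sum(axis=2) == m_xp_i).all()
    assert (counts.sum(axis=0) == joint_i).all()
    return counts


def rake_all(spec: ContingencySpec, tol: float = 1e-10) -> dict[str, ThreeWayTable]:
    """Rake every predictor's three-way table against the published margins."""
    return {
        name: rake_three_way(
            spec.margins_xo[name], spec.margins_xp[name], spec.poison_outcome, tol=tol, predictor=name
        )
        for name in spec.margins_xo
    }


def _ages_for_groups(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ages = np.empty(len(groups), dtype=int)
    for g, (lo, hi) in AGE_BOUNDS.items():
        mask = groups == g
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return ages


def sample_cohort(
    spec: ContingencySpec | None = None,
    mode: str = "exact",
    n: int | None = None,
    seed: int = 0,
    include_cosmetic: bool = False,
) -> pd.DataFrame:
    """Generate a patient-level cohort from the published margins.

    In ``exact`` mode the cohort has exactly ``spec.total`` records and every
    predictor-by-outcome and predictor-by-poison crosstab reproduces the
    published cell counts bit-exactly. In ``sampled`` mode ``n`` records are
    drawn i.i.d. from the raked three-way probabilities. Predictors are
    conditionally independent given (poison_type, outcome); ages are uniform
    integers within the record's age-group bounds. Deterministic given
    ``seed``.
    """
    if spec is None:
        spec = load_printed_margins()
    if mode not in ("exact", "sampled"):
        raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'sampled'")
    if mode == "exact":
        if n is not None and n != spec.total:
            raise ValueError(f"exact mode generates exactly {spec.total} records")
        n = spec.total
    else:
        if n is None:
            n = spec.total
        if n < 0:
            raise ValueError("n must be non-negative")

    tables = rake_all(spec)
    ss = np.random.SeedSequence(seed)
    rng_cells, rng_age, rng_shuffle, rng_cosmetic, *rng_preds = [
        np.random.default_rng(s) for s in ss.spawn(4 + len(PREDICTOR_LEVELS))
    ]
    pred_rngs = dict(zip(PREDICTOR_LEVELS, rng_preds))

    joint = spec.poison_outcome.to_numpy()
    cells = [(p, o) for p in POISON_LEVELS for o in OUTCOME_LEVELS]

    if mode == "exact":
        cell_sizes = {
            (p, o): int(spec.poison_outcome.loc[p, o]) for p, o in cells
        }
    else:
        probs = joint.flatten() / joint.sum()
        draws = rng_cells.choice(len(cells), size=n, p=probs)
        cell_sizes = {cells[k]: int((draws == k).sum()) for k in range(len(cells))}

    frames = []
    for p, o in cells:
        size = cell_sizes[(p, o)]
        if size == 0:
            continue
        pi, oi = POISON_LEVELS.index(p), OUTCOME_LEVELS.index(o)
        data = {"poison_type": np.full(size, p, dtype=object), "outcome": np.full(size, o, dtype=object)}
        for name, table in tables.items():
            levels = np.asarray(table.levels, dtype=object)
            if mode == "exact":
                counts = table.counts[:, pi, oi]
                column = np.repeat(levels, counts)
            else:
                pvec = table.raked[:, pi, oi]
                pvec = pvec / pvec.sum()
                column = pred_rngs[name].choice(levels, size=size, p=pvec)
            pred_rngs[name].shuffle(column)
            data["age_group" if name == "age_group" else name] = column
        frames.append(pd.DataFrame(data))

    if not frames:
        cohort = pd.DataFrame(columns=COHORT_COLUMNS)
        cohort["age_years"] = cohort["age_years"].astype(int)
        return cohort

    cohort = pd.concat(frames, ignore_index=True)
    cohort["age_years"] = _ages_for_groups(cohort["age_group"].to_numpy(), rng_age)
    clinical = np.where(cohort["outcome"] == "died", "abnormal", "normal")
    for name in ("blood_pressure", "pulse", "echo"):
        cohort[name] = clinical

    if include_cosmetic:
        if mode == "exact":
            # exact univariate counts (88.5% rural, 52.6% students), shuffled
            res = np.array(
                ["rural"] * spec.rural_count + ["urban"] * (n - spec.rural_count), dtype=object
            )
            occ = np.array(
                ["student"] * spec.student_count + ["other"] * (n - spec.student_count), dtype=object
            )
            rng_cosmetic.shuffle(res)
            rng_cosmetic.shuffle(occ)
        else:
            res = np.where(rng_cosmetic.random(n) < spec.rural_count / spec.total, "rural", "urban")
            occ = np.where(
                rng_cosmetic.random(n) < spec.student_count / spec.total, "student", "other"
            )
        cohort["residence"] = res
        cohort["occupation"] = occ

    # deterministic split-safe ordering: sorted construction above, then one shuffle
    order = rng_shuffle.permutation(len(cohort))
    cohort = cohort.iloc[order].reset_index(drop=True)
    cols = COHORT_COLUMNS + [c for c in ("residence", "occupation") if c in cohort.columns]
    return cohort[cols]


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check cohort-frame invariants; raise ValueError naming the first bad record."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort frame missing columns {missing}")
    for i, row in enumerate(cohort.itertuples(index=False)):
        rec = PatientRecord(
            **{f: getattr(row, f) for f in COHORT_COLUMNS}
        )
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from exc


def encode_features(
    cohort: pd.DataFrame,
    scaling: str = "minmax",
    age_encoding: str = "years",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode a cohort as a feature matrix and binary label vector.

    Columns, in order: age, sex (male=1), poison_type (AlP=1),
    silver_nitrate (positive=1), cholinesterase (abnormal=1),
    mode (suicidal=1). The label is 1 for died, 0 for recovered. ``scaling``
    in {'minmax','zscore','none'} applies to the age column (the binary
    columns are already 0/1); ``age_encoding`` 'years' uses age in years,
    'group' the ordinal age-group index.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if scaling not in ("minmax", "zscore", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if age_encoding not in ("years", "group"):
        raise ValueError(f"unknown age_encoding {age_encoding!r}")

    X = np.empty((len(cohort), len(FEATURE_ORDER)), dtype=float)
    if age_encoding == "years":
        age = cohort["age_years"].to_numpy(dtype=float)
    else:
        idx = {g: k for k, g in enumerate(AGE_GROUPS)}
        try:
            age = np.array([idx[g] for g in cohort["age_group"]], dtype=float)
        except KeyError as exc:
            bad = cohort.index[~cohort["age_group"].isin(AGE_GROUPS)][0]
            raise ValueError(f"record {bad}: unknown age_group {exc.args[0]!r}") from exc

    if scaling == "minmax":
        span = age.max() - age.min()
        age = (age - age.min()) / span if span > 0 else np.zeros_like(age)
    elif scaling == "zscore":
        sd = age.std()
        age = (age - age.mean()) / sd if sd > 0 else np.zeros_like(age)
    X[:, 0] = age

    allowed = {
        "sex": PREDICTOR_LEVELS["sex"],
        "poison_type": POISON_LEVELS,
        "silver_nitrate": PREDICTOR_LEVELS["silver_nitrate"],
        "cholinesterase": PREDICTOR_LEVELS["cholinesterase"],
        "mode": PREDICTOR_LEVELS["mode"],
    }
    for j, col in enumerate(FEATURE_ORDER[1:], start=1):
        values = cohort[col].to_numpy()
        bad = ~np.isin(values, allowed[col])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"record {cohort.index[i]}: unknown {col} value {values[i]!r}")
        X[:, j] = (values == POSITIVE_CODES[col]).astype(float)

    outcome = cohort["outcome"].to_numpy()
    bad = ~np.isin(outcome, OUTCOME_LEVELS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"record {cohort.index[i]}: unknown outcome value {outcome[i]!r}")
    y = (outcome == "died").astype(int)
    return X, y, list(FEATURE_ORDER)


def plant_signal(
    cohort: pd.DataFrame, noise: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Replace the outcome with a known predictor rule plus label noise.

    The planted rule is: died iff the silver-nitrate test is positive and the
    cholinesterase level is abnormal; each label is then flipped independently
    with probability ``noise``. Clinical flags are updated to keep the
    abnormal-iff-died identity. Used to verify that the end-to-end pipeline
    recovers a learnable structure.
    """
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    rule = (out["silver_nitrate"] == "positive") & (out["cholinesterase"] == "abnormal")
    flips = rng.random(len(out)) < noise
    died = rule.to_numpy() ^ flips
    out["outcome"] = np.where(died, "died", "recovered")
    clinical = np.where(died, "abnormal", "normal")
    for name in ("blood_pressure", "pulse", "echo"):
        out[name] = clinical
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV with the canonical header, UTF-8, LF, no index."""
    cohort.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort_csv`."""
    cohort = pd.read_csv(path)
    validate_cohort(cohort)
    return cohort
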