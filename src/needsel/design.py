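"""Design matrices for the two-equation needs-selection model.

The selection (needs) equation and the conditional barrier equation use
different term lists: for identification the packaged default drops alcohol
consumption, the main age-squared term and the man*age interaction from the
selection equation, and drops exercise, obesity and the woman-specific
age-squared term from the barrier equation.  Age enters centered around a
configurable value (by default the pooled sample mean), and all age
polynomials and gender interactions are formed from the centered variable;
centering is what keeps the variance inflation factors of the polynomial
terms small.  Estimation is carried out on the raw centered-years scale; the
x10 / x1000 scaling of the age rows is applied only when reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "DesignError",
    "DegenerateDesignError",
    "default_spec",
    "build_design",
    "compute_vif",
    "COVARIATE_COLUMNS",
]

#: covariate columns every coded panel must carry
COVARIATE_COLUMNS = [
    "man", "age", "unmarried", "seoul_area", "college", "occupation",
    "income", "mca", "private_insurance", "functional_limitation",
    "smoker", "alcohol", "exercise", "obese", "poor_health", "chronic",
]

#: default selection-equation terms (gender-specific age-squared, no main
#: age-squared, no man*age, no alcohol)
EQ1_TERMS = [
    "const", "man", "age_c", "man_x_age_c_sq", "woman_x_age_c_sq",
    "unmarried", "seoul_area", "college", "occ_blue", "occ_white",
    "inc_medium", "inc_highest", "mca", "private_insurance",
    "functional_limitation", "smoker", "exercise", "obese",
    "poor_health", "chronic",
]

#: default barrier-equation terms (main age-squared plus gender
#: interactions, no exercise, no obesity)
EQ2_TERMS = [
    "const", "man", "age_c", "age_c_sq", "man_x_age_c", "man_x_age_c_sq",
    "unmarried", "seoul_area", "college", "occ_blue", "occ_white",
    "inc_medium", "inc_highest", "mca", "private_insurance",
    "functional_limitation", "smoker", "alcohol", "poor_health", "chronic",
]

#: reporting-time multiplier per term (raw centered-years estimates are
#: multiplied by this before display, so age rows print on a readable scale)
DISPLAY_SCALE = {
    "age_c": 10.0,
    "age_c_sq": 1000.0,
    "man_x_age_c": 10.0,
    "man_x_age_c_sq": 1000.0,
    "woman_x_age_c_sq": 1000.0,
}

TERM_LABELS = {
    "const": "Constant",
    "man": "Man (R: woman)",
    "age_c": "Age, 0",
    "age_c_sq": "Age-squared, 000",
    "man_x_age_c": "Man*age, 0",
    "man_x_age_c_sq": "Man*age-squared, 000",
    "woman_x_age_c_sq": "Woman*age-squared, 000",
    "unmarried": "Unmarried (R: married)",
    "seoul_area": "Seoul metropolitan area",
    "college": "College or higher",
    "occ_blue": "Blue-collar job (R: no job)",
    "occ_white": "White-collar job (R: no job)",
    "inc_medium": "Income: medium (R: lowest quintile)",
    "inc_highest": "Income: highest quintile (R: lowest quintile)",
    "mca": "Medical Care Aid (R: NHI)",
    "private_insurance": "Private health insurance",
    "functional_limitation": "Functional limitation",
    "smoker": "Current smoker",
    "alcohol": "Alcohol consumer",
    "exercise": "Active physical exercise routine",
    "obese": "Obese",
    "poor_health": "Poor self-assessed health",
    "chronic": "Chronic disease",
}


class DesignError(ValueError):
    pass


class DegenerateDesignError(DesignError):
    pass


@dataclass
class ModelSpec:
    """Term lists, centering and reference coding for the two equations."""

    eq1_terms: list = field(default_factory=lambda: list(EQ1_TERMS))
    eq2_terms: list = field(default_factory=lambda: list(EQ2_TERMS))
    reference_alternative: int = 1
    age_center: float | None = None  # None -> unweighted pooled sample mean

    def __post_init__(self):
        if self.reference_alternative not in (1, 2, 3, 4):
            raise DesignError("reference_alternative must be in {1,2,3,4}")

    def to_dict(self) -> dict:
        return {
            "eq1_terms": list(self.eq1_terms),
            "eq2_terms": list(self.eq2_terms),
            "reference_alternative": self.reference_alternative,
            "age_center": self.age_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**{k: d[k] for k in d if k in
                      {"eq1_terms", "eq2_terms", "reference_alternative", "age_center"}})


@dataclass
class DesignMatrices:
    """Row-aligned matrices, outcomes, weights and cluster ids."""

    X1: np.ndarray
    X2: np.ndarray
    y1: np.ndarray
    y2: np.ndarray  # NaN where y1 == 0
    weights: np.ndarray
    cluster_ids: np.ndarray
    eq1_names: list
    eq2_names: list
    age_center: float = 0.0

    @property
    def n_obs(self) -> int:
        return len(self.y1)

    @property
    def n_individuals(self) -> int:
        return len(pd.unique(self.cluster_ids))

    def to_frame(self) -> pd.DataFrame:
        """Flat table for debugging/export."""
        out = pd.DataFrame(self.X1, columns=[f"eq1:{c}" for c in self.eq1_names])
        for j, c in enumerate(self.eq2_names):
            out[f"eq2:{c}"] = self.X2[:, j]
        out["y1"], out["y2"] = self.y1, self.y2
        out["weight"], out["cluster_id"] = self.weights, self.cluster_ids
        return out


def _term_column(term: str, data: pd.DataFrame, age_c: np.ndarray) -> np.ndarray:
    man = data["man"].to_numpy(dtype=float) if "man" in data else None
    if term == "const":
        return np.ones(len(data))
    if term == "age_c":
        return age_c
    if term == "age_c_sq":
        return age_c ** 2
    if term == "man_x_age_c":
        return man * age_c
    if term == "man_x_age_c_sq":
        return man * age_c ** 2
    if term == "woman_x_age_c_sq":
        return (1.0 - man) * age_c ** 2
    if term == "occ_blue":
        return (data["occupation"] == "blue_collar").to_numpy(dtype=float)
    if term == "occ_white":
        return (data["occupation"] == "white_collar").to_numpy(dtype=float)
    if term == "inc_medium":
        return (data["income"] == "medium").to_numpy(dtype=float)
    if term == "inc_highest":
        return (data["income"] == "highest").to_numpy(dtype=float)
    if term in data.columns:
        return data[term].to_numpy(dtype=float)
    raise DesignError(f"unknown term name: {term!r}")


def _build_matrix(terms, data, age_c, check_degenerate=True) -> np.ndarray:
    cols = [_term_column(t, data, age_c) for t in terms]
    X = np.column_stack(cols)
    if check_degenerate:
        for j, t in enumerate(terms):
            if t != "const" and np.ptp(X[:, j]) == 0.0:
                raise DegenerateDesignError(
                    f"term {t!r} is constant in the sample (degenerate design)")
    return X


def build_design(coded: pd.DataFrame, spec: ModelSpec | None = None, *,
                 check_degenerate: bool = True) -> DesignMatrices:
    """Build selection and barrier design matrices from a coded panel.

    ``coded`` must carry ``y1``/``y2`` (see :func:`needsel.outcomes.derive_outcomes`),
    ``person_id``, ``weight`` and the covariate columns.  Rows with missing
    covariates are not allowed; listwise deletion happens upstream.
    ``check_degenerate=False`` skips the constant-column guard (used when
    covariates are deliberately pinned, e.g. on an adjusted-probability grid).
    """
    spec = spec or ModelSpec()
    needed = [c for c in COVARIATE_COLUMNS if c != "age"] + ["age", "y1", "weight", "person_id"]
    missing = [c for c in needed if c not in coded.columns]
    if missing:
        raise DesignError(f"coded data lacks columns: {missing}")
    cov = coded[COVARIATE_COLUMNS]
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise DesignError(f"missing covariate values in columns {bad}; "
                          "apply listwise deletion upstream")

    age = coded["age"].to_numpy(dtype=float)
    center = float(np.mean(age)) if spec.age_center is None else float(spec.age_center)
    age_c = age - center

    X1 = _build_matrix(spec.eq1_terms, coded, age_c, check_degenerate)
    X2 = _build_matrix(spec.eq2_terms, coded, age_c, check_degenerate)
    y1 = coded["y1"].to_numpy(dtype=int)
    y2 = coded["y2"].to_numpy(dtype=float)
    w = coded["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise DesignError("non-positive weights in coded data")
    return DesignMatrices(
        X1=X1, X2=X2, y1=y1, y2=y2, weights=w,
        cluster_ids=coded["person_id"].to_numpy(),
        eq1_names=list(spec.eq1_terms), eq2_names=list(spec.eq2_terms),
        age_center=center,
    )


def default_spec(age_center: float | None = None) -> ModelSpec:
    return ModelSpec(age_center=age_center)


def compute_vif(X: np.ndarray, names: list | None = None) -> pd.Series:
    """Variance inflation factors, 1/(1-R^2), for each non-intercept column.

    Each non-intercept column is regressed on all other columns (including
    the intercept).  Exact collinearity raises :class:`DegenerateDesignError`
    naming the offending columns (their VIF would be infinite).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]
    is_const = [np.ptp(X[:, j]) <= 1e-12 * max(1.0, np.abs(X[:, j]).max())
                for j in range(k)]
    targets = [j for j in range(k) if not is_const[j]]
    if len(targets) < 2:
        raise DesignError("need at least two non-intercept columns")
    vifs = {}
    offenders = []
    for j in targets:
        others = [m for m in range(k) if m != j]
        A = X[:, others]
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        tss = np.sum((y - y.mean()) ** 2)
        rss = float(np.sum(resid ** 2))
        r2 = 1.0 - rss / tss
        if rss / tss < 1e-10:
            offenders.append(names[j])
            vifs[names[j]] = np.inf
        else:
            vifs[names[j]] = 1.0 / (1.0 - r2)
    if offenders:
        raise DegenerateDesignError(
            f"exact collinearity (infinite VIF) in columns: {offenders}")
    return pd.Series(vifs, name="vif")
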