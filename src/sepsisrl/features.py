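"""Feature-set definitions and dimensionality reduction for patient state vectors.

The state space of the MDP is built either on the full 48-variable vector, on an
a-priori clinical subset (all non-laboratory variables, the six cardiorespiratory
variables, or a six-variable low-information reference set), or on the leading
principal components of the standardized full vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

#: Cardiorespiratory variables continuously available from bedside monitoring.
CARDIO_FEATURES: tuple[str, ...] = (
    "heart_rate",
    "systolic_bp",
    "diastolic_bp",
    "shock_index",
    "spo2",
    "mech_vent",
)

#: Low-information reference set (lowest first-principal-component loadings).
BASELINE_FEATURES: tuple[str, ...] = (
    "gender",
    "total_fluid_input",
    "chloride",
    "body_temperature",
    "weight",
    "readmission",
)

#: Laboratory variables: sparse in time, results delayed by assay turnaround.
LAB_FEATURES: tuple[str, ...] = (
    "chloride",
    "potassium",
    "sodium",
    "glucose",
    "creatinine",
    "bun",
    "magnesium",
    "calcium",
    "ionized_calcium",
    "co2",
    "sgot",
    "sgpt",
    "total_bilirubin",
    "albumin",
    "hemoglobin",
    "wbc",
    "platelets",
    "ptt",
    "pt",
    "inr",
    "arterial_ph",
    "pao2",
    "paco2",
    "lactate",
    "base_excess",
    "bicarbonate",
)

_NON_LAB_EXTRA: tuple[str, ...] = (
    "age",
    "elixhauser",
    "sofa",
    "gcs",
    "respiratory_rate",
    "mean_bp",
    "urine_output",
    "cumulative_balance",
    "fio2",
    "sedation",
    "height",
)

#: The full 48-variable state vector: vitals, demographics, labs, fluid balance,
#: comorbidity and severity scores.
FULL_FEATURES: tuple[str, ...] = (
    CARDIO_FEATURES
    + tuple(f for f in BASELINE_FEATURES if f not in LAB_FEATURES)
    + _NON_LAB_EXTRA
    + LAB_FEATURES
)

#: Non-laboratory subset (usable without assay delay).
NO_LAB_FEATURES: tuple[str, ...] = tuple(
    f for f in FULL_FEATURES if f not in LAB_FEATURES
)

assert len(FULL_FEATURES) == 48
assert len(set(FULL_FEATURES)) == 48
assert len(NO_LAB_FEATURES) == 22


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named state representation.

    A-priori sets (``FULL``, ``NO_LAB``, ``CARDIO``, ``BASELINE``) are plain
    column subsets.  PCA sets project the standardized full vector onto leading
    principal components fitted on the training split only: ``PCA80`` keeps the
    25 components explaining ~80% of variance, ``PCA15`` keeps the first 2
    (~15% of variance).
    """

    name: str
    features: tuple[str, ...] | None = None
    n_components: int | None = None

    _REGISTRY = {
        "FULL": {"features": FULL_FEATURES},
        "NO_LAB": {"features": NO_LAB_FEATURES},
        "CARDIO": {"features": CARDIO_FEATURES},
        "BASELINE": {"features": BASELINE_FEATURES},
        "PCA80": {"n_components": 25},
        "PCA15": {"n_components": 2},
    }

    @classmethod
    def from_name(cls, name: str) -> "FeatureSetSpec":
        key = name.upper().replace(" ", "_")
        if key not in cls._REGISTRY:
            raise ValueError(
                f"unknown feature set {name!r}; known: {sorted(cls._REGISTRY)}"
            )
        return cls(name=key, **cls._REGISTRY[key])

    @property
    def is_pca(self) -> bool:
        return self.n_components is not None


class FeatureSetTransformer(BaseEstimator, TransformerMixin):
    """Reduce a trajectory feature matrix to a named state representation.

    For a-priori sets this is a stateless column subset.  For PCA sets the
    standardizer and component loadings are fitted on the training rows passed
    to :meth:`fit` and applied unchanged thereafter (no test-set leakage).

    Parameters
    ----------
    spec : FeatureSetSpec or str
        The representation to produce.

    Attributes
    ----------
    feature_names_in_ : list of str
        Input columns seen at fit.
    feature_names_out_ : list of str
        Output columns (original names, or ``pc1..pcM``).
    scaler_ : StandardScaler, PCA sets only.
    pca_ : PCA, PCA sets only.
    """

    def __init__(self, spec: FeatureSetSpec | str = "FULL"):
        self.spec = spec

    def _resolved(self) -> FeatureSetSpec:
        if isinstance(self.spec, str):
            return FeatureSetSpec.from_name(self.spec)
        return self.spec

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureSetTransformer":
        spec = self._resolved()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of named feature columns")
        self.feature_names_in_ = list(X.columns)
        if spec.is_pca:
            self.scaler_ = StandardScaler().fit(X.to_numpy(dtype=float))
            self.pca_ = PCA(n_components=spec.n_components, svd_solver="full").fit(
                self.scaler_.transform(X.to_numpy(dtype=float))
            )
            self.feature_names_out_ = [
                f"pc{i + 1}" for i in range(spec.n_components)
            ]
        else:
            missing = [f for f in spec.features if f not in X.columns]
            if missing:
                raise ValueError(f"unknown feature name(s): {missing}")
            self.feature_names_out_ = list(spec.features)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        spec = self._resolved()
        if spec.is_pca:
            if list(X.columns) != self.feature_names_in_:
                raise ValueError("columns differ from those seen at fit")
            Z = self.pca_.transform(self.scaler_.transform(X.to_numpy(dtype=float)))
            return pd.DataFrame(Z, columns=self.feature_names_out_, index=X.index)
        return X.loc[:, list(spec.features)]

    def explained_variance_fraction(self) -> float:
        """Cumulative explained-variance ratio of the kept components."""
        return float(np.sum(self.pca_.explained_variance_ratio_))


def select_features(
    table: pd.DataFrame,
    spec: FeatureSetSpec | str,
    train_mask: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Thin functional wrapper: fit on training rows, transform all rows."""
    tf = FeatureSetTransformer(spec)
    fit_rows = table if train_mask is None else table.loc[np.asarray(train_mask)]
    tf.fit(fit_rows)
    return tf.transform(table)
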