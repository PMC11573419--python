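"""Discrete state space and treatment-action grid.

States: feature vectors are standardized (location/scale fitted on training
rows) and partitioned by k-means++ into ``k`` clusters; two extra absorbing
states, ``k`` (survived) and ``k+1`` (dead), terminate every trajectory.

Actions: each treatment (vasopressor rate, IV-fluid volume per 4 h) is
discretized into 5 bins — bin 0 reserved for zero dose, bins 1..4 bounded by
the 25th/50th/75th percentiles of the *nonzero* training doses (including
zeros would collapse the edges whenever zeros dominate).  The composite action
id is ``5 * vaso_bin + fluid_bin``, giving 25 actions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

N_DOSE_BINS = 5
N_ACTIONS = N_DOSE_BINS * N_DOSE_BINS


class StateDiscretizer(BaseEstimator):
    """Map feature rows to discrete state ids ``0..k-1`` (+ absorbing ids).

    Parameters
    ----------
    k : int
        Number of clinical states (clusters); the study design uses 750, or
        250 for reduced feature spaces.
    seed : int
        k-means++ initialization seed; refitting with the same seed and data
        reproduces the centroids bit-for-bit.
    standardize : bool
        Standardize features (fit on training rows) before clustering;
        k-means is scale-sensitive and the variables have heterogeneous units.

    Attributes
    ----------
    centroids_ : (k, d) ndarray in standardized space.
    scaler_ : fitted StandardScaler (or None).
    survived_state_, dead_state_ : absorbing state ids ``k`` and ``k+1``.
    """

    def __init__(self, k: int = 750, seed: int = 0, standardize: bool = True):
        self.k = k
        self.seed = seed
        self.standardize = standardize

    def fit(self, X, y=None) -> "StateDiscretizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] < self.k:
            raise ValueError(
                f"need at least k={self.k} training rows, got {X.shape[0]}"
            )
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Z = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Z = X
        km = KMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            tol=1e-4,
            random_state=self.seed,
        ).fit(Z)
        self.centroids_ = km.cluster_centers_.copy()
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def survived_state_(self) -> int:
        return self.k

    @property
    def dead_state_(self) -> int:
        return self.k + 1

    @property
    def n_states_(self) -> int:
        return self.k + 2

    def transform(self, X) -> np.ndarray:
        """Nearest-centroid (Euclidean) state ids; ties break to the lowest
        centroid index."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got {X.shape}"
            )
        Z = self.scaler_.transform(X) if self.scaler_ is not None else X
        # chunked distance computation keeps memory bounded for large cohorts
        out = np.empty(len(Z), dtype=np.int64)
        step = max(1, 2_000_000 // max(1, self.k))
        for i in range(0, len(Z), step):
            blk = Z[i : i + step]
            d2 = (
                (blk**2).sum(axis=1)[:, None]
                - 2.0 * blk @ self.centroids_.T
                + (self.centroids_**2).sum(axis=1)[None, :]
            )
            out[i : i + step] = np.argmin(d2, axis=1)
        return out

    predict = transform

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "seed": self.seed,
            "standardize": self.standardize,
            "centroids": self.centroids_.tolist(),
        }
        if self.scaler_ is not None:
            d["scaler_mean"] = self.scaler_.mean_.tolist()
            d["scaler_scale"] = self.scaler_.scale_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StateDiscretizer":
        obj = cls(k=d["k"], seed=d["seed"], standardize=d["standardize"])
        obj.centroids_ = np.asarray(d["centroids"], dtype=float)
        obj.n_features_in_ = obj.centroids_.shape[1]
        obj.scaler_ = None
        if "scaler_mean" in d:
            sc = StandardScaler()
            sc.mean_ = np.asarray(d["scaler_mean"])
            sc.scale_ = np.asarray(d["scaler_scale"])
            sc.var_ = sc.scale_**2
            sc.n_features_in_ = len(sc.mean_)
            obj.scaler_ = sc
        return obj


class ActionDiscretizer(BaseEstimator):
    """Map (vasopressor, fluid) dose pairs to composite action ids 0..24.

    Bin 0 is exactly zero dose.  Bins ``b`` in 1..4 cover the right-closed
    intervals ``(edge_{b-1}, edge_b]`` with ``edge_0 = 0`` and
    ``edge_4 = inf``, where the interior edges are the 25th/50th/75th
    percentiles (linear interpolation) of the nonzero training doses.

    Attributes
    ----------
    vaso_edges_, fluid_edges_ : (3,) ndarrays of percentile edges.
    """

    def fit(self, vaso_doses, fluid_doses) -> "ActionDiscretizer":
        self.vaso_edges_ = self._edges(np.asarray(vaso_doses, float), "vasopressor")
        self.fluid_edges_ = self._edges(np.asarray(fluid_doses, float), "fluid")
        return self

    @staticmethod
    def _edges(doses: np.ndarray, label: str) -> np.ndarray:
        nz = doses[doses > 0]
        if nz.size == 0:
            raise ValueError(f"all {label} training doses are zero")
        return np.percentile(nz, [25.0, 50.0, 75.0])

    @staticmethod
    def _bin(doses: np.ndarray, edges: np.ndarray) -> np.ndarray:
        b = np.where(
            doses <= 0, 0, np.searchsorted(edges, doses, side="left") + 1
        )
        return b.astype(np.int64)

    def vaso_bins(self, doses) -> np.ndarray:
        return self._bin(np.asarray(doses, float), self.vaso_edges_)

    def fluid_bins(self, doses) -> np.ndarray:
        return self._bin(np.asarray(doses, float), self.fluid_edges_)

    def transform(self, vaso_doses, fluid_doses) -> np.ndarray:
        return N_DOSE_BINS * self.vaso_bins(vaso_doses) + self.fluid_bins(
            fluid_doses
        )

    def to_dict(self) -> dict:
        return {
            "vaso_edges": self.vaso_edges_.tolist(),
            "fluid_edges": self.fluid_edges_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActionDiscretizer":
        obj = cls()
        obj.vaso_edges_ = np.asarray(d["vaso_edges"], float)
        obj.fluid_edges_ = np.asarray(d["fluid_edges"], float)
        return obj


def action_components(action_ids) -> tuple[np.ndarray, np.ndarray]:
    """Split composite action ids into (vaso_bin, fluid_bin)."""
    a = np.asarray(action_ids)
    return a // N_DOSE_BINS, a % N_DOSE_BINS


def assign_states(
    table: pd.DataFrame,
    model: StateDiscretizer,
    feature_cols: list[str],
) -> dict[object, np.ndarray]:
    """Per-patient state-id sequences terminated by the absorbing outcome.

    ``table`` must be a trajectory table with ``patient_id``, ``bin_index``,
    ``outcome`` and the feature columns; the returned sequence for a patient
    with ``T`` clinical bins has length ``T + 1``, its last element being the
    survived (``k``) or dead (``k+1``) absorbing id.
    """
    ids = model.transform(table[feature_cols].to_numpy(float))
    sequences: dict[object, np.ndarray] = {}
    table = table.reset_index(drop=True)
    for pid, grp in table.groupby("patient_id", sort=True):
        order = grp.bin_index.to_numpy().argsort()
        seq = ids[grp.index.to_numpy()[order]]
        outcome = grp.outcome.iloc[0]
        terminal = (
            model.survived_state_ if outcome == "survived" else model.dead_state_
        )
        sequences[pid] = np.append(seq, terminal)
    return sequences


def save_models(
    path, state_model: StateDiscretizer, action_grid: ActionDiscretizer
) -> None:
    Path(path).write_text(
        json.dumps(
            {"state_model": state_model.to_dict(), "action_grid": action_grid.to_dict()},
            indent=1,
        )
    )


def load_models(path) -> tuple[StateDiscretizer, ActionDiscretizer]:
    d = json.loads(Path(path).read_text())
    return (
        StateDiscretizer.from_dict(d["state_model"]),
        ActionDiscretizer.from_dict(d["action_grid"]),
    )
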