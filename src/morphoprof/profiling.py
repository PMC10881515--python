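"""Profile aggregation, sphering batch correction and treatment-effect scores.

Aggregation hierarchy: single-cell features are aggregated with the
coordinatewise *median* at field-of-view (site) level, site profiles with the
*mean* to well level, and well profiles with the *mean* across replicate
wells to treatment level. Well rows containing NA features are dropped
before any further step.

Sphering (ZCA whitening) is fitted on negative-control well profiles only:
with centered controls X (n x d), Sigma = X^T X / n = U Delta U^T and the
correction matrix is Q = U (Delta + lambda)^(-1/2) U^T, applied to every
well as t' = Q (t - mu). Directions that vary a lot among controls —
presumed technical — are shrunk; directions unseen in controls are
amplified. lambda defaults to 1e-3; the treatment-effect procedure uses
1e-2.

Treatment effect is a crude average-treatment-effect estimate: the per-well
Euclidean distance to the plate's median control profile, Z-scored against
the plate's control-distance distribution, averaged over replicate wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProfileTable",
    "SpheringTransform",
    "make_profile_table",
    "aggregate_profiles",
    "fit_sphering",
    "apply_sphering",
    "save_sphering",
    "load_sphering",
    "cosine_similarity",
    "effect_scores",
    "select_effect_band",
    "DEFAULT_LAMBDA",
    "EFFECT_LAMBDA",
]

DEFAULT_LAMBDA = 1e-3
EFFECT_LAMBDA = 1e-2

METADATA_PREFIX = "Metadata_"
_LEVELS = ("cell", "site", "well", "treatment")


@dataclass
class ProfileTable:
    """Feature vectors at one aggregation level with metadata columns."""

    data: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def feature_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if not str(c).startswith(METADATA_PREFIX)
            and c not in ("Treatment", "Control", "Concentration")
        ]

    @property
    def features(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    def with_features(self, values: np.ndarray) -> "ProfileTable":
        data = self.data.copy()
        data[self.feature_columns] = values
        return ProfileTable(data=data, level=self.level)


def make_profile_table(
    features: np.ndarray, metadata: pd.DataFrame, level: str = "cell"
) -> ProfileTable:
    """Assemble a ProfileTable from a feature array and aligned metadata."""
    metadata = metadata.reset_index(drop=True)
    feat = pd.DataFrame(
        np.asarray(features, dtype=float),
        columns=[f"f{i:04d}" for i in range(np.asarray(features).shape[1])],
    )
    return ProfileTable(data=pd.concat([metadata, feat], axis=1), level=level)


def _agg(table: ProfileTable, keys: list[str], how: str, level: str,
         carry: list[str]) -> ProfileTable:
    feat_cols = table.feature_columns
    grouped = table.data.groupby(keys, sort=True)
    agg_feat = grouped[feat_cols].median() if how == "median" else grouped[feat_cols].mean()
    meta = grouped[carry].first() if carry else None
    data = pd.concat([meta, agg_feat], axis=1).reset_index() if meta is not None else agg_feat.reset_index()
    return ProfileTable(data=data, level=level)


def aggregate_profiles(table: ProfileTable, level: str) -> ProfileTable:
    """Aggregate a cell-level table up to ``site``, ``well`` or ``treatment``.

    cell -> site: coordinatewise median; site -> well: mean; well ->
    treatment: mean over replicate wells. Sites with zero cells simply have
    no row; wells with NA features are dropped (with a warning) before
    aggregation continues.
    """
    if _LEVELS.index(level) <= _LEVELS.index(table.level):
        raise ValueError(f"cannot aggregate {table.level} to {level}")
    t = table
    if t.level == "cell" and _LEVELS.index(level) >= 1:
        t = _agg(
            t,
            ["Metadata_Plate", "Metadata_Well", "Metadata_Site"],
            "median",
            "site",
            [c for c in ("Treatment", "Control", "Concentration") if c in t.data.columns],
        )
    if t.level == "site" and _LEVELS.index(level) >= 2:
        t = _agg(
            t,
            ["Metadata_Plate", "Metadata_Well"],
            "mean",
            "well",
            [c for c in ("Treatment", "Control", "Concentration") if c in t.data.columns],
        )
    if t.level == "well" and _LEVELS.index(level) >= 3:
        na_rows = t.data[t.feature_columns].isna().any(axis=1)
        if na_rows.any():
            warnings.warn(f"dropping {int(na_rows.sum())} well profiles with NA features")
            t = ProfileTable(data=t.data.loc[~na_rows].reset_index(drop=True), level="well")
        before = set(t.data["Treatment"].unique())
        t = _agg(t, ["Treatment"], "mean", "treatment",
                 [c for c in ("Control",) if c in t.data.columns])
        lost = before - set(t.data["Treatment"].unique())
        if lost:
            warnings.warn(f"treatments with no surviving wells omitted: {sorted(lost)}")
    return t


def drop_na_wells(table: ProfileTable) -> ProfileTable:
    """Remove well rows containing any NA feature value."""
    na_rows = table.data[table.feature_columns].isna().any(axis=1)
    if na_rows.any():
        warnings.warn(f"dropping {int(na_rows.sum())} profiles with NA features")
    return ProfileTable(data=table.data.loc[~na_rows].reset_index(drop=True), level=table.level)


@dataclass
class SpheringTransform:
    """Fitted ZCA correction operator (matrix Q, regularization, control mean)."""

    Q: np.ndarray  # (d, d), symmetric
    lam: float
    mu: np.ndarray  # control mean (d,)
    n_controls: int

    @property
    def d(self) -> int:
        return self.Q.shape[0]


def fit_sphering(
    control_profiles: ProfileTable | np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    center: bool = True,
) -> SpheringTransform:
    """Fit the sphering transform from negative-control well profiles only.

    With ``center`` (default) the control mean is subtracted before the
    covariance Sigma = X^T X / n; ``center=False`` reproduces the literal
    uncentered second-moment formula.
    """
    X = control_profiles.features if isinstance(control_profiles, ProfileTable) else np.asarray(control_profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < 2:
        raise ValueError(f"need >= 2 control wells to fit sphering, got {n}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    mu = X.mean(axis=0) if center else np.zeros(d)
    Xc = X - mu
    sigma = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(sigma)
    evals = np.clip(evals, 0.0, None)
    if lam == 0 and np.any(evals < 1e-12 * max(evals.max(), 1.0)):
        raise ValueError(
            "singular control covariance with lambda=0; use lambda > 0 "
            "(required whenever n_controls <= d)"
        )
    Q = (evecs * (evals + lam) ** -0.5) @ evecs.T
    return SpheringTransform(Q=Q, lam=float(lam), mu=mu, n_controls=n)


def apply_sphering(
    transform: SpheringTransform, profiles: ProfileTable | np.ndarray
) -> ProfileTable | np.ndarray:
    """Correct well profiles: t' = Q (t - mu), metadata preserved."""
    if isinstance(profiles, ProfileTable):
        X = profiles.features
    else:
        X = np.asarray(profiles, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != transform.d:
        raise ValueError(
            f"profile dimensionality {X.shape[1]} != transform dimensionality {transform.d}"
        )
    corrected = (X - transform.mu) @ transform.Q
    if isinstance(profiles, ProfileTable):
        return profiles.with_features(corrected)
    return corrected


def save_sphering(transform: SpheringTransform, path) -> None:
    """Persist (Q, mu, lambda, n) as an array archive with a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, Q=transform.Q, mu=transform.mu)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"lambda": transform.lam, "n_controls": transform.n_controls,
                    "d": transform.d})
    )


def load_sphering(path) -> SpheringTransform:
    """Load a :func:`save_sphering` archive."""
    import json
    from pathlib import Path

    path = Path(path)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as z:
        Q, mu = z["Q"], z["mu"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpheringTransform(Q=Q, lam=float(meta["lambda"]), mu=mu,
                             n_controls=int(meta["n_controls"]))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(A, B) = A.B / (||A|| ||B||); undefined (error) for zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(a @ b / (na * nb))


def effect_scores(well_profiles: ProfileTable) -> pd.DataFrame:
    """Z-scored distance-to-control effect estimate per treatment.

    For every plate: take the median control profile; compute each well's
    Euclidean distance to it; Z-score treated-well distances against the
    mean/sd (population sd) of the control-well distances of that plate.
    The treatment score is the mean Z across its replicate wells. The
    returned frame has one row per treatment; per-well audit values are in
    ``attrs['wells']``. Plates with < 2 control wells are skipped with a
    warning; a zero control-distance sd raises (degenerate controls).
    """
    if well_profiles.level != "well":
        raise ValueError("effect_scores expects well-level profiles")
    df = well_profiles.data
    feat_cols = well_profiles.feature_columns
    well_rows = []
    for plate, group in df.groupby("Metadata_Plate"):
        controls = group[group["Control"].astype(bool)]
        if len(controls) < 2:
            warnings.warn(f"plate {plate} has <2 control wells; skipped")
            continue
        m_p = controls[feat_cols].median().to_numpy()
        dists = np.linalg.norm(group[feat_cols].to_numpy() - m_p, axis=1)
        ctrl_mask = group["Control"].astype(bool).to_numpy()
        mean_c, sd_c = dists[ctrl_mask].mean(), dists[ctrl_mask].std()
        if sd_c == 0:
            raise ValueError(f"degenerate controls on plate {plate}: zero distance sd")
        z = (dists - mean_c) / sd_c
        for (_, row), dist, zz in zip(group.iterrows(), dists, z):
            well_rows.append(
                {
                    "Metadata_Plate": plate,
                    "Metadata_Well": row["Metadata_Well"],
                    "Treatment": row["Treatment"],
                    "Control": bool(row["Control"]),
                    "distance": float(dist),
                    "z": float(zz),
                }
            )
    wells = pd.DataFrame(well_rows)
    if wells.empty:
        raise ValueError("no plate had enough control wells")
    treated = wells[~wells["Control"]]
    scores = (
        treated.groupby("Treatment")["z"].mean().rename("score").reset_index()
    )
    scores.attrs["wells"] = wells
    return scores


def select_effect_band(
    scores: pd.DataFrame, band: str, frac: float = 0.2
) -> list[str]:
    """Select the weak / median / strong 20% band of treatments by effect.

    Treatments are sorted ascending by score (ties broken by treatment id);
    ``weak`` is the first k, ``strong`` the last k and ``median`` the k
    centered at the middle rank, with k = round(frac * N).
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if band not in ("weak", "median", "strong"):
        raise ValueError(f"unknown band {band!r}")
    ordered = scores.sort_values(["score", "Treatment"], kind="mergesort")
    names = ordered["Treatment"].tolist()
    n = len(names)
    k = int(round(frac * n))
    if k < 1:
        raise ValueError(f"frac {frac} selects no treatments out of {n}")
    if band == "weak":
        return names[:k]
    if band == "strong":
        return names[n - k :]
    start = (n - k) // 2
    return names[start : start + k]
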