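"""Untargeted branch: feature table, carrier normalization, greedy RLS
feature selection under nested leave-cell-out cross-validation, PCA and
accurate-mass annotation.

Reporter intensities acquired under automatic gain control are compositional:
each MS2 scan is rescaled to a fixed ion budget, so only intra-scan ratios
carry information.  Dividing every cell channel by the carrier channel of the
same scan removes the per-scan scale exactly.

Feature selection is greedy forward selection with regularized (ridge) least
squares: starting from the empty set, each step adds the feature whose
addition minimizes the leave-one-out cross-validation (LOOCV) mean squared
error, computed in closed form from the ridge hat-matrix diagonal rather than
by n refits.  Because the cohort contains three injection replicates per cell,
the outer evaluation loop holds out all replicates of one cell at a time
(leave-cell-out), re-running the selection on every training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from sklearn.decomposition import PCA

from .channels import PROTON_MASS, TMT10_TAG_MASS
from .reporter_extraction import ReporterReading

# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Untargeted feature × sample matrix with missingness.

    ``features``: DataFrame indexed by feature_id with columns ``mz``, ``rt``.
    ``values``: DataFrame (features × samples); NaN marks a missing
    (not-detected) value.
    ``samples``: DataFrame indexed by sample_id with columns ``cell_id``,
    ``cell_type``, ``replicate_id``; every sample belongs to exactly one cell.
    """

    features: pd.DataFrame
    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.features.index):
            raise ValueError("values rows must match the feature index")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns must match the sample index")
        if self.samples[["cell_id", "replicate_id"]].duplicated().any():
            raise ValueError("duplicate (cell_id, replicate_id) sample")

    @property
    def n_cells(self) -> int:
        return self.samples["cell_id"].nunique()

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.features.loc[feature_ids],
            self.values.loc[feature_ids],
            self.samples,
        )


def presence_filter(table: FeatureTable, min_fraction: float = 0.25) -> FeatureTable:
    """Keep features detected in at least ``min_fraction`` of distinct cells.

    A feature is "present" in a cell when it is non-missing and nonzero in at
    least one replicate of that cell; the boundary is inclusive (a feature in
    exactly 25 % of cells survives the default filter).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if table.values.empty:
        raise ValueError("empty feature table")
    cells = table.samples["cell_id"]
    present = (table.values.notna() & (table.values > 0))
    per_cell = present.T.groupby(cells).any().T  # feature × cell
    frac = per_cell.sum(axis=1) / table.n_cells
    keep = frac[frac >= min_fraction].index
    return table.subset_features(keep)


def carrier_normalize(
    reading: ReporterReading,
    carrier_channel: str,
    cell_channels: list[str],
) -> dict[str, float | None]:
    """Divide each cell channel by the same scan's carrier intensity.

    Removes the per-scan AGC scale factor exactly.  A nonpositive carrier
    marks every value of the scan missing (``None``) rather than dividing.
    """
    carrier = reading.intensities[carrier_channel]
    if carrier <= 0:
        return {c: None for c in cell_channels}
    return {c: reading.intensities[c] / carrier for c in cell_channels}


# ---------------------------------------------------------------------------
# Regularized least squares with exact LOOCV
# ---------------------------------------------------------------------------


def _check_design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("X must be 2-D with >= 1 feature")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in X")
    return x


def rls_fit(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solution w = argmin ‖Xw − y‖² + λ‖w‖², intercept unpenalized.

    The intercept is handled by centering, which is equivalent to an
    unpenalized constant column.  Returns ``(weights, intercept)``;
    multi-output ``y`` (n × q) is supported column-wise.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    x = _check_design(x)
    y = np.asarray(y, dtype=float)
    xm = x.mean(axis=0)
    ym = np.atleast_1d(y.mean(axis=0))
    xc = x - xm
    yc = y - y.mean(axis=0)
    k = xc.T @ xc + lam * np.eye(x.shape[1])
    w = np.linalg.solve(k, xc.T @ yc)
    b = ym - xm @ w
    return w, b


def _hat_diag(x: np.ndarray, lam: float) -> np.ndarray:
    """Leverages h_ii of the ridge smoother with unpenalized intercept."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    k = xc.T @ xc + lam * np.eye(x.shape[1])
    h = np.einsum("ij,ji->i", xc, np.linalg.solve(k, xc.T))
    return 1.0 / n + h


def loocv_mse(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Exact leave-one-out MSE of the ridge fit via the leverage shortcut.

    Uses e_i^loo = (y_i − ŷ_i)/(1 − h_ii), which for a fixed penalty equals
    the residual of an explicit refit without observation i.  Multi-output
    ``y`` averages over all outputs.
    """
    x = _check_design(x)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("LOOCV requires n >= 3")
    w, b = rls_fit(x, y, lam)
    resid = y - (x @ w + b)
    h = _hat_diag(x, lam)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("degenerate leverage h_ii = 1")
    loo = resid / (1.0 - h)[:, None] if resid.ndim == 2 else resid / (1.0 - h)
    return float(np.mean(loo**2))


@dataclass
class RlsModel:
    """Greedy-RLS selection result: ordered selected features, ridge weights
    on that set, and the LOOCV MSE after each addition."""

    selected: list[int]
    lam: float
    weights: np.ndarray
    intercept: np.ndarray
    loocv_path: list[float] = field(default_factory=list)


def greedy_forward_select(
    x: np.ndarray, y: np.ndarray, lam: float = 1.0, k: int = 100
) -> RlsModel:
    """Greedy forward selection: each step adds the feature minimizing the
    LOOCV MSE of the ridge fit on the enlarged set.

    Ties are broken toward the lowest feature index, making the full path
    deterministic.
    """
    x = _check_design(x)
    n, p = x.shape
    if k > p:
        raise ValueError(f"k={k} exceeds {p} available features")
    selected: list[int] = []
    path: list[float] = []
    remaining = list(range(p))
    for _ in range(k):
        best_j, best_mse = None, np.inf
        for j in remaining:
            mse = loocv_mse(x[:, selected + [j]], y, lam)
            if mse < best_mse:
                best_j, best_mse = j, mse
        selected.append(best_j)
        remaining.remove(best_j)
        path.append(best_mse)
    w, b = rls_fit(x[:, selected], y, lam)
    return RlsModel(selected, lam, w, b, path)


# ---------------------------------------------------------------------------
# Nested leave-cell-out cross-validation
# ---------------------------------------------------------------------------


def prepare_matrix(
    table: FeatureTable, missing: str = "zero"
) -> tuple[np.ndarray, list, list]:
    """Samples × features matrix after log2(x+1) with a missing-value strategy.

    Strategies: ``zero`` (missing = not detected → 0 before the log),
    ``median`` (per-feature median of observed values), ``drop`` (discard
    features with any missing value).
    Returns ``(X, feature_ids, sample_ids)``.
    """
    vals = table.values.copy()
    if missing == "zero":
        vals = vals.fillna(0.0)
    elif missing == "median":
        med = vals.median(axis=1)
        if med.isna().any():
            raise ValueError("feature with no observed values; cannot median-fill")
        vals = vals.T.fillna(med).T
    elif missing == "drop":
        vals = vals.dropna(axis=0)
        if vals.empty:
            raise ValueError("all features contain missing values")
    else:
        raise ValueError(f"unknown missing-value strategy {missing!r}")
    x = np.log2(1.0 + vals.to_numpy(dtype=float)).T
    return x, list(vals.index), list(table.values.columns)


def _standardize_train(x_train, x_test):
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x_train - mu) / sd, (x_test - mu) / sd


def _one_vs_all_targets(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return np.where(labels[:, None] == classes[None, :], 1.0, -1.0)


@dataclass
class FoldResult:
    cell_id: str
    true_labels: list[str]
    predicted: list[str]
    accuracy: float
    selected: list


@dataclass
class NestedCvResult:
    folds: list[FoldResult]
    accuracy: float
    classes: list[str]


def nested_leave_cell_out(
    table: FeatureTable,
    k: int = 10,
    lam: float = 1.0,
    missing: str = "zero",
) -> NestedCvResult:
    """Leave-cell-out outer loop around greedy-RLS selection.

    Every outer fold holds out all replicates of one cell; feature
    standardization, greedy selection (LOOCV-MSE summed over the one-vs-all
    ±1 targets) and the per-class ridge classifiers use training samples
    only.  Predictions take the argmax of the class scores; fold accuracy is
    the fraction of held-out replicates classified correctly, and the
    reported accuracy is the average over folds.
    """
    labels = table.samples["cell_type"].to_numpy()
    if pd.isna(labels).any():
        raise ValueError("missing cell_type label")
    classes = np.array(sorted(set(labels)))
    if classes.size < 2:
        raise ValueError(">= 2 cell types required")
    counts = table.samples.groupby("cell_id").size()
    if counts.nunique() != 1:
        raise ValueError("every cell must have the same replicate count")
    x_all, _, sample_ids = prepare_matrix(table, missing)
    cell_of = table.samples["cell_id"].to_numpy()
    folds = []
    for cell in pd.unique(cell_of):
        test = cell_of == cell
        x_tr, x_te = _standardize_train(x_all[~test], x_all[test])
        y_tr = _one_vs_all_targets(labels[~test], classes)
        model = greedy_forward_select(x_tr, y_tr, lam=lam, k=min(k, x_tr.shape[1]))
        scores = x_te[:, model.selected] @ model.weights + model.intercept
        pred = classes[np.argmax(scores, axis=1)]
        true = labels[test]
        folds.append(
            FoldResult(
                cell_id=cell,
                true_labels=list(true),
                predicted=list(pred),
                accuracy=float(np.mean(pred == true)),
                selected=list(model.selected),
            )
        )
    return NestedCvResult(
        folds=folds,
        accuracy=float(np.mean([f.accuracy for f in folds])),
        classes=list(classes),
    )


def select_features(
    table: FeatureTable,
    k: int = 100,
    lam: float = 1.0,
    min_presence: float = 0.25,
    missing: str = "zero",
) -> tuple[pd.DataFrame, RlsModel]:
    """Presence-filter, standardize, and run greedy RLS on the full cohort.

    Returns a ranked DataFrame (rank, feature_id, mz, rt, loocv_mse) plus the
    fitted model.
    """
    filtered = presence_filter(table, min_presence)
    x, feature_ids, _ = prepare_matrix(filtered, missing)
    x, _ = _standardize_train(x, x)
    labels = filtered.samples["cell_type"].to_numpy()
    classes = np.array(sorted(set(labels)))
    y = _one_vs_all_targets(labels, classes)
    model = greedy_forward_select(x, y, lam=lam, k=min(k, x.shape[1]))
    rows = []
    for rank, j in enumerate(model.selected, start=1):
        fid = feature_ids[j]
        rows.append(
            {
                "rank": rank,
                "feature_id": fid,
                "mz": filtered.features.loc[fid, "mz"],
                "rt": filtered.features.loc[fid, "rt"],
                "loocv_mse": model.loocv_path[rank - 1],
            }
        )
    return pd.DataFrame(rows), model


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_project(
    table: FeatureTable,
    n_components: int | None = None,
    scale: bool = False,
    missing: str = "zero",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (optionally unit-variance) PCA of the prepared sample matrix.

    Returns per-sample scores and the explained-variance fractions, which sum
    to 1 when all components are retained.
    """
    x, _, sample_ids = prepare_matrix(table, missing)
    if scale:
        x, _ = _standardize_train(x, x)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Accurate-mass annotation
# ---------------------------------------------------------------------------

_COMPOUND_FORMULAS = {
    "glycine": "C2H5NO2",
    "alanine": "C3H7NO2",
    "serine": "C3H7NO3",
    "proline": "C5H9NO2",
    "valine": "C5H11NO2",
    "threonine": "C4H9NO3",
    "cysteine": "C3H7NO2S",
    "leucine": "C6H13NO2",
    "asparagine": "C4H8N2O3",
    "aspartic acid": "C4H7NO4",
    "glutamine": "C5H10N2O3",
    "glutamic acid": "C5H9NO4",
    "lysine": "C6H14N2O2",
    "methionine": "C5H11NO2S",
    "histidine": "C6H9N3O2",
    "phenylalanine": "C9H11NO2",
    "arginine": "C6H14N4O2",
    "tyrosine": "C9H11NO3",
    "tryptophan": "C11H12N2O2",
    "cystine": "C6H12N2O4S2",
    "taurine": "C2H7NO3S",
    "putrescine": "C4H12N2",
    "gamma-aminobutyric acid": "C4H9NO2",
    "creatine": "C4H9N3O2",
}


def compound_table() -> pd.DataFrame:
    """Bundled toy table of common cellular amines with exact neutral masses.

    Columns: name, formula, monoisotopic_mass, has_nitrogen.  Masses are
    computed from elemental composition at call time.
    """
    rows = [
        {
            "name": name,
            "formula": formula,
            "monoisotopic_mass": _pmass.calculate_mass(formula=formula),
            "has_nitrogen": "N" in formula,
        }
        for name, formula in _COMPOUND_FORMULAS.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class Annotation:
    feature_id: str
    compound: str | None
    mass_error_mda: float | None
    level: str  # "2", "4" or "unannotated"


def annotate_by_mass(
    feature_id: str,
    precursor_mz: float,
    compounds: pd.DataFrame,
    n_labels: int = 1,
    charge: int = 1,
    tol_mda: float = 5.0,
    spectral_match: str | None = None,
) -> Annotation:
    """Annotate a feature by accurate precursor mass after removing the
    TMT10plex label mass.

    neutral mass = m/z·z − z·m_proton − n_labels·m_tag; candidates are
    nitrogen-containing compounds within ±tol_mda.  A mass-only match is
    Level 4; Level 2 is reserved for caller-supplied spectral matches.
    """
    if compounds.empty:
        raise ValueError("empty compound table")
    if n_labels not in (1, 2):
        raise ValueError("n_labels must be 1 or 2")
    if spectral_match is not None:
        return Annotation(feature_id, spectral_match, None, "2")
    neutral = precursor_mz * charge - charge * PROTON_MASS - n_labels * TMT10_TAG_MASS
    cand = compounds[compounds["has_nitrogen"]]
    errors = (cand["monoisotopic_mass"] - neutral).abs() * 1000.0
    within = errors[errors <= tol_mda]
    if within.empty:
        return Annotation(feature_id, None, None, "unannotated")
    best = within.idxmin()
    return Annotation(
        feature_id, cand.loc[best, "name"], float(errors.loc[best]), "4"
    )
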