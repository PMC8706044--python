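"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

OPLS separates the variation of the feature matrix X into a part
correlated with the class structure Y (predictive components) and a part
orthogonal to it.  Class membership enters as a centered dummy matrix,
so a single model covers multi-class designs.  Model quality is
summarized by R2X/R2Y (cumulative explained variation) and Q2
(cross-validated predictive ability); the S-plot of covariance- vs
correlation-scaled loadings of the first predictive component ranks
features as discriminating (|p(corr)| large) or common across classes
(|p(corr)| small).

The latent-variable algorithms (NIPALS PLS2 and the orthogonal filter)
are implemented here directly; scikit-learn is used only for fold
assignment in cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import ConsensusFeature, Tolerances

SCALINGS = ("uv", "pareto", "center")


@dataclass
class DataMatrix:
    """Sample x feature intensity matrix with metadata.

    ``values``: DataFrame indexed by sample id, columns named ``mz@rt``.
    ``sample_meta``: DataFrame with the same index carrying at least
    ``solvent`` and ``instrument`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the sample index")
        if self.values.isna().any().any():
            raise ValueError("missing values must be imputed (0) before modelling")

    def classes(self, by: str = "solvent") -> np.ndarray:
        return self.sample_meta[by].to_numpy()

    def to_csv(self, path) -> None:
        out = pd.concat([self.sample_meta[["solvent", "instrument"]], self.values], axis=1)
        out.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path) -> "DataMatrix":
        df = pd.read_csv(path, index_col="sample")
        meta = df[["solvent", "instrument"]]
        return cls(values=df.drop(columns=["solvent", "instrument"]), sample_meta=meta)


def build_data_matrix(
    consensus_sets: dict[tuple[str, str], Sequence[ConsensusFeature]],
    tol: Tolerances = Tolerances(),
) -> DataMatrix:
    """Align consensus features across samples into one matrix.

    Keys are (solvent, instrument); each sample contributes one matrix
    row per injection (its per-injection intensities).  Features from all
    samples are pooled and grouped greedily (descending intensity) within
    the ppm/RT tolerances; a feature absent from a sample is 0.
    """
    pool = []  # (intensity, mz, rt, key, feature)
    for key, feats in consensus_sets.items():
        for f in feats:
            pool.append((f.intensity, f.mz, f.rt, key, f))
    order = sorted(range(len(pool)), key=lambda i: (-pool[i][0], pool[i][1], i))
    used = [False] * len(pool)
    groups = []
    for i in order:
        if used[i]:
            continue
        _, mz0, rt0, _, _ = pool[i]
        members = []
        for j in order:
            if used[j]:
                continue
            _, mz, rt, _, _ = pool[j]
            if abs(mz - mz0) / mz0 * 1e6 <= tol.ppm_tol and abs(rt - rt0) <= tol.rt_tol:
                members.append(j)
        for j in members:
            used[j] = True
        groups.append(members)

    n_inj = max((len(pool[m[0]][4].intensities) for m in groups), default=0)
    row_index, meta_rows = [], []
    for (solvent, instrument) in consensus_sets:
        for inj in range(n_inj):
            row_index.append(f"{instrument}|{solvent}|i{inj}")
            meta_rows.append({"solvent": solvent, "instrument": instrument, "injection": inj})
    values = np.zeros((len(row_index), len(groups)))
    col_names = []
    row_of = {}
    for r, name in enumerate(row_index):
        row_of[name] = r
    for g, members in enumerate(groups):
        mzs = [pool[j][1] for j in members]
        rts = [pool[j][2] for j in members]
        col_names.append(f"{np.mean(mzs):.4f}@{np.mean(rts):.2f}")
        for j in members:
            _, _, _, (solvent, instrument), f = pool[j]
            for inj, inten in enumerate(f.intensities):
                values[row_of[f"{instrument}|{solvent}|i{inj}"], g] = inten
    idx = pd.Index(row_index, name="sample")
    return DataMatrix(values=pd.DataFrame(values, index=idx, columns=col_names),
                      sample_meta=pd.DataFrame(meta_rows, index=idx))


# ---------------------------------------------------------------------------
# scaling and dummy coding


def _dummy(classes: np.ndarray) -> tuple[np.ndarray, list]:
    labels = sorted(set(classes))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes for discriminant analysis")
    Y = np.zeros((len(classes), len(labels)))
    for j, lab in enumerate(labels):
        Y[np.asarray(classes) == lab, j] = 1.0
    return Y, labels


def _fit_scaler(X: np.ndarray, scaling: str, log_transform: bool):
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    Xw = np.log10(1.0 + X) if log_transform else X.astype(float)
    mean = Xw.mean(axis=0)
    sd = Xw.std(axis=0, ddof=1) if Xw.shape[0] > 1 else np.zeros(Xw.shape[1])
    if scaling == "uv":
        keep = sd > 0
        scale = np.where(keep, sd, 1.0)
    elif scaling == "pareto":
        keep = sd > 0
        scale = np.where(keep, np.sqrt(sd), 1.0)
    else:
        keep = np.ones(Xw.shape[1], dtype=bool)
        scale = np.ones(Xw.shape[1])
    if scaling != "center" and not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant feature column(s) "
                      f"under {scaling} scaling")
    return {"mean": mean, "scale": scale, "keep": keep,
            "scaling": scaling, "log": log_transform}


def _apply_scaler(X: np.ndarray, sc: dict) -> np.ndarray:
    Xw = np.log10(1.0 + X) if sc["log"] else X.astype(float)
    Z = (Xw - sc["mean"]) / sc["scale"]
    return Z[:, sc["keep"]]


# ---------------------------------------------------------------------------
# latent-variable algorithms


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int,
                 tol: float = 1e-12, max_iter: int = 1000):
    """Standard NIPALS PLS2 with X- and Y-deflation.

    Returns weights W, X-loadings P, Y-loadings Q (columns per
    component) and scores T on the supplied (already scaled) data.
    """
    Xd = X.copy()
    Yd = Y.copy()
    n, p = X.shape
    k = Y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((k, n_components))
    T = np.zeros((n, n_components))
    for a in range(n_components):
        if np.allclose(Yd, 0):
            break
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        t = q = None
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                break
            q = Yd.T @ t / tt
            nq = np.linalg.norm(q)
            if nq == 0:
                break
            u = Yd @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        if t is None or q is None:
            break
        tt = t @ t
        if tt == 0:
            break
        pvec = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
    return W, P, Q, T, Xd, Yd


def _y_weight_basis(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the X-weight subspace predictive of Y."""
    C = X.T @ Y
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return U[:, :rank]


@dataclass
class OplsModel:
    """Fitted OPLS-DA model with scores, loadings and quality metrics."""

    class_labels: list
    scores: np.ndarray           # predictive scores t, (n, n_predictive)
    scores_orth: np.ndarray      # orthogonal scores t_o, (n, n_orthogonal)
    weights: np.ndarray          # predictive weights w
    loadings: np.ndarray         # predictive X-loadings p
    loadings_orth: np.ndarray    # orthogonal X-loadings p_o
    weights_orth: np.ndarray     # orthogonal weights w_o
    y_loadings: np.ndarray       # q, (n_classes, n_predictive)
    coef: np.ndarray             # regression coefficients on filtered X
    y_mean: np.ndarray
    r2x_cum: float
    r2y_cum: float
    q2_cum: Optional[float] = None
    scaler: dict = field(default_factory=dict, repr=False)
    feature_names: list = field(default_factory=list, repr=False)
    scaled_x: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_predictive(self) -> int:
        return self.scores.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.scores_orth.shape[1]

    def filter_orthogonal(self, Z: np.ndarray) -> np.ndarray:
        """Remove the fitted orthogonal variation from scaled data."""
        Zf = Z.copy()
        for a in range(self.n_orthogonal):
            t_o = Zf @ self.weights_orth[:, a]
            Zf = Zf - np.outer(t_o, self.loadings_orth[:, a])
        return Zf

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Continuous dummy-Y predictions for new raw samples."""
        Z = _apply_scaler(np.asarray(X_raw, dtype=float), self.scaler)
        return self.filter_orthogonal(Z) @ self.coef + self.y_mean

    def summary(self) -> dict:
        return {
            "classes": list(map(str, self.class_labels)),
            "n_predictive": self.n_predictive,
            "n_orthogonal": self.n_orthogonal,
            "r2x_cum": self.r2x_cum,
            "r2y_cum": self.r2y_cum,
            "q2_cum": self.q2_cum,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def fit_opls_da(
    X, classes,
    n_predictive: int = 1,
    n_orthogonal: int = 1,
    scaling: str = "uv",
    log_transform: bool = False,
) -> OplsModel:
    """Fit an OPLS-DA model on a raw intensity matrix.

    ``X`` is samples x features (array or :class:`DataMatrix` values);
    ``classes`` the per-sample labels (dummy-coded internally).  Before
    each predictive extraction, ``n_orthogonal`` components uncorrelated
    with the class structure are removed from X; the remaining variation
    is modelled by NIPALS PLS2 with ``n_predictive`` components.  With
    ``n_orthogonal=0`` the model is exactly standard PLS-DA.
    """
    feature_names = []
    if isinstance(X, DataMatrix):
        feature_names = list(X.values.columns)
        X = X.values.to_numpy()
    elif isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    Y, labels = _dummy(classes)
    if X.shape[0] < len(labels):
        raise ValueError("need at least as many samples as classes")
    if n_predictive < 1:
        raise ValueError("n_predictive must be >= 1")

    scaler = _fit_scaler(X, scaling, log_transform)
    Z = _apply_scaler(X, scaler)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ssx_total = float((Z ** 2).sum())
    ssy_total = float((Yc ** 2).sum())

    p = Z.shape[1]
    Zd = Z.copy()
    W_o = np.zeros((p, n_orthogonal))
    P_o = np.zeros((p, n_orthogonal))
    T_o = np.zeros((Z.shape[0], n_orthogonal))
    n_o = 0
    for a in range(n_orthogonal):
        basis = _y_weight_basis(Zd, Yc)
        if basis.shape[1] == 0:
            break
        w = basis[:, 0]
        t = Zd @ w
        tt = t @ t
        if tt == 0:
            break
        pvec = Zd.T @ t / tt
        w_o = pvec - basis @ (basis.T @ pvec)
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no Y-orthogonal structure left in this direction
        w_o /= n_wo
        t_o = Zd @ w_o
        p_o = Zd.T @ t_o / (t_o @ t_o)
        Zd = Zd - np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
        n_o = a + 1
    W_o, P_o, T_o = W_o[:, :n_o], P_o[:, :n_o], T_o[:, :n_o]

    W, P, Q, T, X_res, Y_res = _nipals_pls2(Zd, Yc, n_predictive)
    # regression coefficients of the filtered X on Y: B = W (P'W)^-1 Q'
    PtW = P.T @ W
    coef = W @ np.linalg.pinv(PtW) @ Q.T

    r2x = 1.0 - float((X_res ** 2).sum()) / ssx_total if ssx_total > 0 else 0.0
    r2y = 1.0 - float((Y_res ** 2).sum()) / ssy_total if ssy_total > 0 else 0.0
    return OplsModel(
        class_labels=labels, scores=T, scores_orth=T_o,
        weights=W, loadings=P, loadings_orth=P_o, weights_orth=W_o,
        y_loadings=Q, coef=coef, y_mean=y_mean,
        r2x_cum=float(r2x), r2y_cum=float(r2y),
        scaler=scaler, feature_names=feature_names, scaled_x=Z,
    )


def cross_validated_q2(
    X, classes,
    folds: int = 7,
    seed: int = 0,
    n_predictive: int = 1,
    n_orthogonal: int = 1,
    scaling: str = "uv",
    log_transform: bool = False,
) -> float:
    """Cumulative Q2 = 1 - PRESS/SS by class-stratified cross-validation.

    Each fold refits the scaling and the full OPLS model on the training
    samples only; PRESS accumulates squared errors of the held-out dummy
    predictions, SS the squared deviations of held-out Y from the
    training mean.  When the smallest class has fewer samples than
    ``folds``, the fold count is reduced with a warning.
    """
    if isinstance(X, DataMatrix):
        X = X.values.to_numpy()
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(classes, return_counts=True)
    min_class = int(counts.min())
    if min_class < folds:
        warnings.warn(f"reducing folds from {folds} to {min_class} "
                      "(smallest class size)")
        folds = min_class
    if folds < 2:
        raise ValueError("smallest class has fewer than 2 samples")

    Y_full, _ = _dummy(classes)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    ss = 0.0
    for train, test in skf.split(X, classes):
        model = fit_opls_da(X[train], classes[train],
                            n_predictive=n_predictive, n_orthogonal=n_orthogonal,
                            scaling=scaling, log_transform=log_transform)
        Y_hat = model.predict(X[test])
        Y_test = Y_full[test]
        press += float(((Y_test - Y_hat) ** 2).sum())
        ss += float(((Y_test - Y_full[train].mean(axis=0)) ** 2).sum())
    return 1.0 - press / ss


@dataclass(frozen=True)
class SPlotPoint:
    """S-plot coordinates of one feature."""

    feature: str
    p1: float       # covariance-scaled loading, cov(t1, x_j)/sd(t1)
    pcorr1: float   # correlation loading, corr(t1, x_j)
    zero_variance: bool = False


def s_plot(model: OplsModel, X=None) -> list[SPlotPoint]:
    """Covariance and correlation of each feature with the first
    predictive score vector.

    Uses the scaled training matrix stored on the model (or scales ``X``
    with the model's preprocessing).  Zero-variance features get
    p(corr) = 0 with a flag instead of NaN.
    """
    if X is None:
        Z = model.scaled_x
        if Z is None:
            raise ValueError("model stores no training data; pass X explicitly")
    else:
        if isinstance(X, DataMatrix):
            X = X.values.to_numpy()
        elif isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        Z = _apply_scaler(np.asarray(X, dtype=float), model.scaler)
    t1 = model.scores[:, 0]
    n = len(t1)
    t1c = t1 - t1.mean()
    sd_t = t1.std(ddof=1)
    names = model.feature_names or [f"f{j}" for j in range(Z.shape[1])]
    if model.scaler.get("keep") is not None and len(names) != Z.shape[1]:
        names = [nm for nm, k in zip(names, model.scaler["keep"]) if k]
    pts = []
    for j in range(Z.shape[1]):
        xj = Z[:, j]
        xc = xj - xj.mean()
        cov = float(t1c @ xc) / (n - 1)
        sd_x = xj.std(ddof=1)
        if sd_x == 0 or sd_t == 0:
            pts.append(SPlotPoint(names[j], 0.0, 0.0, zero_variance=True))
        else:
            pts.append(SPlotPoint(names[j], cov / sd_t, cov / (sd_t * sd_x)))
    return pts


def select_common_features(
    splot: Sequence[SPlotPoint],
    pcorr_max: float = 0.1,
    balance_tol: float = 0.05,
    class_splots: Optional[tuple[Sequence[SPlotPoint], Sequence[SPlotPoint]]] = None,
) -> list[SPlotPoint]:
    """Features common across classes: small, balanced |p(corr)|.

    Selects features with |p(corr)1| <= ``pcorr_max``; when per-class
    S-plots are supplied, additionally requires the two class-wise
    p(corr) values to agree within ``balance_tol``.  Sorted by |p(corr)|.
    """
    selected = [p for p in splot if abs(p.pcorr1) <= pcorr_max]
    if class_splots is not None:
        a = {p.feature: p.pcorr1 for p in class_splots[0]}
        b = {p.feature: p.pcorr1 for p in class_splots[1]}
        selected = [p for p in selected
                    if p.feature in a and p.feature in b
                    and abs(a[p.feature] - b[p.feature]) <= balance_tol]
    return sorted(selected, key=lambda p: abs(p.pcorr1))


def splot_frame(points: Sequence[SPlotPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": p.feature, "p1": p.p1, "pcorr1": p.pcorr1,
        "zero_variance": p.zero_variance,
    } for p in points])
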