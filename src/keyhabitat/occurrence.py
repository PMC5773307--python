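"""Presence-only occurrence modelling.

Fits a logistic occurrence probability surface to presence-only records by
maximizing the conditional likelihood

    l(beta) = sum_i log psi(x_i; beta) - n * log( mean_z psi(z; beta) )

where ``psi = logistic(beta0 + beta'x)`` and the mean runs over every
study-area cell. Model selection uses AICc across replicated 75/25
calibration/validation partitions; evaluation uses pseudo-absences drawn
outside the study area (never inside the likelihood); the occurrence
threshold is the mean max-kappa statistic of the chosen replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.special import expit, logsumexp

from .grid import BinaryMask, GridLayer

log = logging.getLogger(__name__)

#: representatives preferred when collapsing covariate clusters
DEFAULT_PRIORITY = ("TREE", "AI", "BIO02", "BIO03", "BIO07", "BIO10",
                    "BIO17", "BIO19")


# ---------------------------------------------------------------------------
# data containers

@dataclass
class PresenceSet:
    """Presence-only point records (grid coordinates, km) with years."""

    x: np.ndarray
    y: np.ndarray
    year: np.ndarray
    source: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        if not (len(self.x) == len(self.y) == len(self.year)):
            raise ValueError("x, y, year must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, idx: np.ndarray) -> "PresenceSet":
        src = None if self.source is None else np.asarray(self.source)[idx]
        return PresenceSet(self.x[idx], self.y[idx], self.year[idx], src)

    def filter_years(self, min_year: int) -> "PresenceSet":
        return self.subset(np.flatnonzero(self.year >= min_year))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y, "year": self.year})
        if self.source is not None:
            df["source"] = self.source
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceSet":
        src = df["source"].to_numpy() if "source" in df else None
        return cls(df["x"].to_numpy(), df["y"].to_numpy(),
                   df["year"].to_numpy(), src)


@dataclass
class CovariateStack:
    """Named covariate layers on a shared grid with transform and
    standardization state learned over study-area cells."""

    names: list[str]
    layers: dict[str, GridLayer]
    study_mask: BinaryMask | None = None
    transforms: dict[str, str] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in self.names if n not in self.layers]
        if missing:
            raise KeyError(f"missing covariate layers: {missing}")
        base = self.layers[self.names[0]]
        for n in self.names[1:]:
            base.require_same_geometry(self.layers[n])
        if self.study_mask is not None:
            base.require_same_geometry(self.study_mask)

    @property
    def grid(self) -> GridLayer:
        return self.layers[self.names[0]]

    def cell_mask(self) -> np.ndarray:
        """Valid-data cells, restricted to the study area when one is set."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for n in self.names:
            mask &= self.layers[n].mask
        if self.study_mask is not None:
            mask &= self.study_mask.as_bool()
        return mask

    def _processed(self, name: str) -> np.ndarray:
        vals = self.layers[name].values.copy()
        vals = _apply_transform(vals, self.transforms.get(name, "none"), name)
        if name in self.standardization:
            mu, sd = self.standardization[name]
            vals = (vals - mu) / sd
        return vals

    def design_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_cells, p) matrix of processed covariates over valid cells."""
        names = self.names if names is None else names
        mask = self.cell_mask()
        return np.column_stack([self._processed(n)[mask] for n in names])

    def values_at(self, points: PresenceSet,
                  names: list[str] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        row, col = self.grid.cell_of(points.x, points.y)
        nr, nc = self.grid.shape
        if ((row < 0) | (row >= nr) | (col < 0) | (col >= nc)).any():
            raise ValueError("presence point outside the grid")
        mask = self.cell_mask()
        if not mask[row, col].all():
            raise ValueError("presence point falls in a nodata / outside-"
                             "study-area cell")
        return np.column_stack(
            [self._processed(n)[row, col] for n in names])


def _apply_transform(vals: np.ndarray, how: str, name: str) -> np.ndarray:
    if how == "none":
        return vals
    if how == "sqrt":
        if np.nanmin(vals) < 0:
            raise ValueError(f"layer {name}: negative value under sqrt transform")
        return np.sqrt(vals)
    if how == "square":
        return np.square(vals)
    raise ValueError(f"unknown transform {how!r}")


# ---------------------------------------------------------------------------
# covariate screening

def cluster_covariates(
    stack: CovariateStack,
    threshold: float = 0.6,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    always_keep: tuple[str, ...] = ("TREE", "AI"),
    linkage: str = "average",
) -> tuple[list[list[str]], list[str]]:
    """Group covariates by |Pearson r| and pick one representative each.

    Average-linkage hierarchical clustering on distance 1 - |r| over
    study-area cells, cut so that between-cluster |r| < ``threshold``.
    Returns ``(clusters, representatives)``; names in ``always_keep`` are
    retained even when they are not their cluster's representative.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two covariates to cluster")
    X = np.column_stack([stack.layers[n].values[stack.cell_mask()]
                         for n in names])
    sd = X.std(axis=0)
    for n, s in zip(names, sd):
        if s == 0:
            raise ValueError(f"layer {n} is constant over the study area")
    r = np.corrcoef(X, rowvar=False)
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(names), k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")

    order = {n: i for i, n in enumerate(priority)}
    clusters: list[list[str]] = []
    reps: list[str] = []
    for lab in sorted(set(labels)):
        members = [n for n, l in zip(names, labels) if l == lab]
        members.sort(key=lambda n: (order.get(n, len(order)), n))
        clusters.append(members)
        reps.append(members[0])
    for n in always_keep:
        if n in names and n not in reps:
            reps.append(n)
    reps.sort(key=lambda n: (order.get(n, len(order)), n))
    return clusters, reps


def transform_and_standardize(
    stack: CovariateStack,
    skewed_names: list[str],
    method: str = "sqrt",
) -> CovariateStack:
    """Apply the skew transform to the named layers, then center/scale every
    layer to zero mean and unit variance over study-area cells.

    The stated purpose of the transform is skew reduction; ``sqrt`` is the
    default (``square`` is available but increases right skew).
    """
    transforms = {n: (method if n in skewed_names else "none")
                  for n in stack.names}
    out = CovariateStack(list(stack.names), dict(stack.layers),
                         stack.study_mask, transforms, {})
    mask = out.cell_mask()
    standardization = {}
    for n in out.names:
        vals = _apply_transform(out.layers[n].values.copy(),
                                transforms[n], n)[mask]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise ValueError(f"layer {n} has zero variance after transform")
        standardization[n] = (mu, sd)
    out.standardization = standardization
    return out


# ---------------------------------------------------------------------------
# replicated partitioning

@dataclass
class ReplicateSplit:
    replicate_id: int
    calibration: PresenceSet
    validation: PresenceSet
    seed: int


def partition_records(
    presences: PresenceSet,
    frac: float = 0.75,
    n_replicates: int = 5,
    seed: int = 0,
) -> list[ReplicateSplit]:
    """Independent uniform random calibration/validation partitions.

    Calibration size is ``round(frac * n)`` with half-up rounding.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    n = len(presences)
    if n < 8:
        raise ValueError("need at least 8 records to partition")
    n_cal = int(np.floor(frac * n + 0.5))
    rng = np.random.default_rng(seed)
    splits = []
    for rep in range(1, n_replicates + 1):
        perm = rng.permutation(n)
        splits.append(ReplicateSplit(
            replicate_id=rep,
            calibration=presences.subset(np.sort(perm[:n_cal])),
            validation=presences.subset(np.sort(perm[n_cal:])),
            seed=seed,
        ))
    return splits


# ---------------------------------------------------------------------------
# likelihood fitting

@dataclass
class MaxLikeFit:
    formula: list[str]
    beta: np.ndarray
    loglik: float
    aicc: float
    converged: bool
    replicate_id: int | None = None
    n_calibration: int = 0
    transforms: dict[str, str] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)


def _neg_loglik_and_grad(beta: np.ndarray, X: np.ndarray,
                         Z: np.ndarray) -> tuple[float, np.ndarray]:
    # log psi = -log(1 + exp(-eta)) and a log-sum-exp over cells keep the
    # objective finite on badly scaled (raw) covariates
    n = X.shape[0]
    eta_x = beta[0] + X @ beta[1:]
    eta_z = beta[0] + Z @ beta[1:]
    log_psi_x = -np.logaddexp(0.0, -eta_x)
    log_psi_z = -np.logaddexp(0.0, -eta_z)
    log_sum_z = logsumexp(log_psi_z)
    ll = log_psi_x.sum() - n * (log_sum_z - np.log(Z.shape[0]))
    psi_x = expit(eta_x)
    psi_z = expit(eta_z)
    X1 = np.column_stack([np.ones(n), X])
    Z1 = np.column_stack([np.ones(Z.shape[0]), Z])
    w_z = np.exp(log_psi_z - log_sum_z) * (1.0 - psi_z)
    grad = X1.T @ (1.0 - psi_x) - n * (Z1.T @ w_z)
    return -ll, -grad


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2K + 2K(K+1)/(n-K-1); +inf when n <= K+1."""
    if n - k - 1 <= 0:
        return float("inf")
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_maxlike(
    calibration: PresenceSet,
    stack: CovariateStack,
    formula: list[str],
    replicate_id: int | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    beta_bound: float = 25.0,
) -> MaxLikeFit:
    """Maximize the presence-only log-likelihood by quasi-Newton ascent from
    ``beta = 0``. Optimizer failure yields ``converged=False``, never an
    exception.

    Convergence requires the gradient infinity-norm below ``gtol``
    rescaled by the calibration size (the log-likelihood is O(n), so an
    absolute 1e-6 is unattainable in double precision at large n) and all
    coefficients finite with ``|beta| < beta_bound`` on the standardized
    scale — quasi-separation drives coefficients beyond any such bound
    while the gradient still vanishes along the divergent path.
    """
    X = stack.values_at(calibration, formula)
    Z = stack.design_matrix(formula)
    n = X.shape[0]
    k = len(formula) + 1
    beta0 = np.zeros(k)
    try:
        res = optimize.minimize(
            _neg_loglik_and_grad, beta0, args=(X, Z), jac=True,
            method="BFGS", options={"gtol": gtol, "maxiter": maxiter})
        success = bool(res.success)
        if not success:
            # BFGS can stop with "precision loss" a hair from the optimum;
            # polish before declaring failure
            res2 = optimize.minimize(
                _neg_loglik_and_grad, res.x, args=(X, Z), jac=True,
                method="L-BFGS-B",
                options={"gtol": gtol, "maxiter": maxiter})
            if res2.fun <= res.fun:
                res = res2
            success = bool(res2.success)
        beta = res.x
        ll = -float(res.fun)
        gnorm = float(np.max(np.abs(
            _neg_loglik_and_grad(beta, X, Z)[1])))
        converged = gnorm < max(gtol * n, 1e-6) \
            and np.all(np.isfinite(beta)) \
            and np.max(np.abs(beta)) < beta_bound
    except (ValueError, FloatingPointError):  # pragma: no cover - defensive
        beta, ll, converged = beta0, -float("inf"), False
    return MaxLikeFit(
        formula=list(formula), beta=np.asarray(beta), loglik=ll,
        aicc=aicc(ll, k, n), converged=converged, replicate_id=replicate_id,
        n_calibration=n, transforms=dict(stack.transforms),
        standardization=dict(stack.standardization))


def select_best_model(fits: dict[str, list[MaxLikeFit]]) -> str:
    """Pick the formula that converged with the lowest AICc in the most
    replicates; ties go to the formula with fewest covariates."""
    if len(fits) < 2:
        if len(fits) == 1:
            (name, reps), = fits.items()
            if any(f.converged for f in reps):
                return name
            raise ValueError("the only candidate formula never converged")
        raise ValueError("need at least one candidate formula")
    n_rep = max(len(v) for v in fits.values())
    wins = {name: 0 for name in fits}
    any_converged = False
    for rep in range(n_rep):
        cands = {name: reps[rep] for name, reps in fits.items()
                 if rep < len(reps) and reps[rep].converged}
        if not cands:
            continue
        any_converged = True
        best = min(cands, key=lambda nm: cands[nm].aicc)
        wins[best] += 1
    if not any_converged:
        raise ValueError("no formula converged in any replicate")
    return min(wins, key=lambda nm: (-wins[nm], len(fits[nm][0].formula), nm))


# ---------------------------------------------------------------------------
# evaluation against pseudo-absences

@dataclass
class EvalMetrics:
    auc: float
    cor: float
    maxsss_threshold: float
    maxsss_value: float
    max_kappa: float
    kappa_argmax_threshold: float
    replicate_id: int | None = None


def _candidate_thresholds(psi: np.ndarray) -> np.ndarray:
    uniq = np.unique(psi)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.unique(np.concatenate([uniq, mids]))


def _kappa(tp: float, fp: float, fn: float, tn: float) -> float:
    total = tp + fp + fn + tn
    po = (tp + tn) / total
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total**2
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def threshold_metrics(psi_pres: np.ndarray,
                      psi_abs: np.ndarray) -> pd.DataFrame:
    """Confusion-based statistics at every candidate threshold (all unique
    predicted values plus midpoints). Positive prediction is ``psi >= t``."""
    psi = np.concatenate([psi_pres, psi_abs])
    ts = _candidate_thresholds(psi)
    npres, nabs = len(psi_pres), len(psi_abs)
    rows = []
    for t in ts:
        tp = float((psi_pres >= t).sum())
        fp = float((psi_abs >= t).sum())
        fn = npres - tp
        tn = nabs - fp
        sens = tp / npres
        spec = tn / nabs
        rows.append((t, sens, spec, sens + spec, _kappa(tp, fp, fn, tn)))
    return pd.DataFrame(rows, columns=["threshold", "sens", "spec",
                                       "sss", "kappa"])


def evaluate_fit(
    fit: MaxLikeFit,
    validation: PresenceSet,
    pseudoabsences: PresenceSet,
    stack: CovariateStack,
) -> EvalMetrics:
    """AUC (rank statistic), point-biserial cor, max kappa, and the maxSSS
    threshold for predicted psi on validation presences vs pseudo-absences."""
    if len(validation) == 0:
        raise ValueError("empty validation set")
    if len(pseudoabsences) == 0:
        raise ValueError("empty pseudo-absence set")
    psi_pres = predict_points(fit, validation, stack)
    psi_abs = predict_points(fit, pseudoabsences, stack)

    # Mann-Whitney AUC with ties counted half
    auc = (np.sum(psi_pres[:, None] > psi_abs[None, :])
           + 0.5 * np.sum(psi_pres[:, None] == psi_abs[None, :])) \
        / (len(psi_pres) * len(psi_abs))
    labels = np.concatenate([np.ones(len(psi_pres)), np.zeros(len(psi_abs))])
    psi = np.concatenate([psi_pres, psi_abs])
    if psi.std() == 0 or labels.std() == 0:
        cor = 0.0
    else:
        cor = float(np.corrcoef(psi, labels)[0, 1])

    tm = threshold_metrics(psi_pres, psi_abs)
    i_sss = int(tm["sss"].idxmax())
    i_kap = int(tm["kappa"].idxmax())
    return EvalMetrics(
        auc=float(auc), cor=cor,
        maxsss_threshold=float(tm.loc[i_sss, "threshold"]),
        maxsss_value=float(tm.loc[i_sss, "sss"]),
        max_kappa=float(tm.loc[i_kap, "kappa"]),
        kappa_argmax_threshold=float(tm.loc[i_kap, "threshold"]),
        replicate_id=fit.replicate_id)


def rank_replicates(metrics: list[EvalMetrics]) -> list[int]:
    """Replicate ids ordered best-first by AUC, then cor, then maxSSS."""
    ordered = sorted(metrics, key=lambda m: (-m.auc, -m.cor, -m.maxsss_value))
    return [m.replicate_id for m in ordered]


@dataclass
class ThresholdSelection:
    selected_replicates: list[int]
    t_psi: float


def select_threshold(metrics: list[EvalMetrics],
                     chosen: list[int]) -> ThresholdSelection:
    """Occurrence threshold = arithmetic mean of the max-kappa statistics of
    the chosen replicates."""
    if not chosen:
        raise ValueError("empty replicate choice")
    by_id = {m.replicate_id: m for m in metrics}
    missing = [c for c in chosen if c not in by_id]
    if missing:
        raise KeyError(f"unknown replicate ids {missing}")
    t = float(np.mean([by_id[c].max_kappa for c in chosen]))
    return ThresholdSelection(selected_replicates=list(chosen), t_psi=t)


# ---------------------------------------------------------------------------
# prediction

def predict_points(fit: MaxLikeFit, points: PresenceSet,
                   stack: CovariateStack) -> np.ndarray:
    X = stack.values_at(points, fit.formula)
    return expit(fit.beta[0] + X @ fit.beta[1:])


def predict_surface(fit: MaxLikeFit, stack: CovariateStack) -> GridLayer:
    """Per-cell psi = logistic(beta0 + beta'x); nodata propagates.

    ``stack`` must carry the same covariate names, transforms and
    standardization constants used in training (use
    :func:`apply_training_state` on raw fine-resolution layers).
    """
    missing = [n for n in fit.formula if n not in stack.layers]
    if missing:
        raise KeyError(f"missing covariates for prediction: {missing}")
    for n in fit.formula:
        if stack.transforms.get(n, "none") != fit.transforms.get(n, "none"):
            raise ValueError(f"transform mismatch for covariate {n}")
        if n in fit.standardization and \
                stack.standardization.get(n) != fit.standardization[n]:
            raise ValueError(f"standardization mismatch for covariate {n}")
    grid = stack.grid
    mask = stack.cell_mask()
    eta = np.full(grid.shape, np.nan)
    eta[mask] = fit.beta[0]
    for b, name in zip(fit.beta[1:], fit.formula):
        eta[mask] += b * stack._processed(name)[mask]
    out = np.full(grid.shape, grid.nodata)
    out[mask] = expit(eta[mask])
    return GridLayer(out, grid.cell_size, grid.origin, grid.nodata)


def apply_training_state(
    fine_layers: dict[str, GridLayer],
    trained: CovariateStack,
    study_mask: BinaryMask | None = None,
) -> CovariateStack:
    """Build a prediction stack that reuses the training transforms and
    standardization constants on new (e.g. fine-resolution) raw layers."""
    return CovariateStack(
        names=[n for n in trained.names if n in fine_layers],
        layers=dict(fine_layers), study_mask=study_mask,
        transforms=dict(trained.transforms),
        standardization=dict(trained.standardization))


def generate_pseudoabsences(outside: BinaryMask, n: int,
                            seed: int = 0) -> PresenceSet:
    """Uniform random cells from an 'outside the study area' mask; points at
    cell centers; evaluation only, never used in the likelihood."""
    rows, cols = np.nonzero(outside.values)
    if len(rows) == 0:
        raise ValueError("outside mask is empty")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=len(rows) < n)
    x = outside.origin[0] + (cols[idx] + 0.5) * outside.cell_size
    y = outside.origin[1] + (rows[idx] + 0.5) * outside.cell_size
    return PresenceSet(x, y, np.zeros(n, dtype=int))
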