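"""Uncertainty estimation, calibration, and evaluation.

Estimation sources: deep ensembles (inter-member variance of the mean,
plus the mean of member variances when members carry a mean-variance
head), Monte Carlo dropout (variance over stochastic passes), the
mean-variance head itself, the evidential normal-inverse-gamma head
(aleatoric + epistemic), the round-robin pairwise-divergence variant for
spectral ensembles, and predicted probabilities for classifiers.

Regression calibrations rescale the variance-like quantity so held-out
standardized residuals behave like the assumed distribution; they never
change the predicted mean.  Classification calibrations are monotone maps
of the raw score, so rankings (hence AUROC) are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .encoder import PropertyModel
from .training import MoleculeDataset, Scaler
from .losses import evidential_variances, sid_loss, UndefinedMetricError

MIN_CALIBRATION_POINTS = 10
DEFAULT_DROPOUT_PASSES = 30
DEFAULT_ENCE_BINS = 10


@dataclass
class UncertaintyBundle:
    """Per-prediction mean and variance-like uncertainty with provenance."""

    mean: np.ndarray                 # (n, n_tasks)
    unc: np.ndarray                  # (n, n_tasks), >= 0
    source: str
    calibration: dict | None = None
    member_vars: np.ndarray | None = None   # (m, n, n_tasks) for mve ensembles

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.unc = np.atleast_2d(np.asarray(self.unc, dtype=np.float64))
        if np.any(self.unc < 0):
            raise ValueError("uncertainties must be nonnegative")

    def with_unc(self, unc: np.ndarray, calibration: dict) -> "UncertaintyBundle":
        return _dc_replace(self, unc=np.atleast_2d(unc), calibration=calibration)


# ---------------------------------------------------------------------------
def _member_outputs(models: list[PropertyModel], dataset: MoleculeDataset,
                    scaler: Scaler, rng=None) -> tuple[np.ndarray, np.ndarray | None]:
    """(means (m,n,t), vars (m,n,t) or None) per ensemble member."""
    cols = dataset.column_batches()
    spec = models[0].spec
    spectra_mask = (dataset.mask.astype(np.float64)
                    if spec.task == "spectra" else None)
    means, mvars = [], []
    for model in models:
        out = model.forward(cols, dataset.features, rng,
                            spectra_mask=spectra_mask)["output"].data
        if spec.task == "regression":
            n = spec.n_tasks
            if spec.loss == "mve":
                means.append(scaler.inverse(out[:, :n]))
                mvars.append(out[:, n:] * (scaler.stds ** 2
                                           if scaler.stds is not None else 1.0))
            elif spec.loss == "evidential":
                means.append(scaler.inverse(out[:, :n]))
                alea, epi = evidential_variances(out[:, n:2 * n],
                                                 out[:, 2 * n:3 * n],
                                                 out[:, 3 * n:])
                s2 = scaler.stds ** 2 if scaler.stds is not None else 1.0
                mvars.append((alea + epi) * s2)
            else:
                means.append(scaler.inverse(out))
        else:
            means.append(out)
    return np.stack(means), (np.stack(mvars) if mvars else None)


def estimate(models: PropertyModel | list[PropertyModel],
             dataset: MoleculeDataset, method: str,
             scaler: Scaler | None = None,
             n_passes: int = DEFAULT_DROPOUT_PASSES,
             seed: int = 0) -> UncertaintyBundle:
    """Build an :class:`UncertaintyBundle` for ``dataset``.

    ``method``: ensemble | dropout | mve | evidential | classification |
    spectra_roundrobin.
    """
    if isinstance(models, PropertyModel):
        models = [models]
    scaler = scaler or Scaler()
    spec = models[0].spec

    if method == "ensemble":
        if len(models) < 2:
            raise ValueError("ensemble uncertainty needs >= 2 submodels")
        means, mvars = _member_outputs(models, dataset, scaler)
        mean = means.mean(axis=0)
        unc = means.var(axis=0)
        if mvars is not None:  # law of total variance
            unc = unc + mvars.mean(axis=0)
        return UncertaintyBundle(mean, unc, "ensemble", member_vars=mvars)

    if method == "dropout":
        model = models[0]
        rate = model.encoder_config.dropout
        rng = np.random.default_rng(seed)
        passes = []
        for _ in range(n_passes):
            m, _ = _member_outputs([model], dataset, scaler,
                                   rng=rng if rate > 0 else None)
            passes.append(m[0])
        passes = np.stack(passes)
        return UncertaintyBundle(passes.mean(axis=0), passes.var(axis=0),
                                 "dropout")

    if method == "mve":
        if spec.loss != "mve":
            raise ValueError("mve uncertainty requires a model trained "
                             "with the mve loss")
        means, mvars = _member_outputs(models, dataset, scaler)
        unc = mvars.mean(axis=0)
        if len(models) > 1:
            unc = unc + means.var(axis=0)
        return UncertaintyBundle(means.mean(axis=0), unc, "mve",
                                 member_vars=mvars)

    if method == "evidential":
        if spec.loss != "evidential":
            raise ValueError("evidential uncertainty requires the "
                             "evidential loss")
        means, mvars = _member_outputs(models, dataset, scaler)
        return UncertaintyBundle(means.mean(axis=0), mvars.mean(axis=0),
                                 "evidential", member_vars=mvars)

    if method == "classification":
        if spec.task not in ("binary", "multiclass"):
            raise ValueError("classification uncertainty requires a "
                             "classification task")
        means, _ = _member_outputs(models, dataset, scaler)
        prob = means.mean(axis=0)
        return UncertaintyBundle(prob, prob, "classification")

    if method == "spectra_roundrobin":
        if spec.task != "spectra":
            raise ValueError("spectra_roundrobin requires a spectra task")
        if len(models) < 2:
            raise ValueError("spectral ensemble variance needs >= 2 submodels")
        means, _ = _member_outputs(models, dataset, scaler)
        m = len(models)
        n = means.shape[1]
        pair_sid = np.zeros(n)
        n_pairs = 0
        for i in range(m):
            for j in range(i + 1, m):
                for r in range(n):
                    pair_sid[r] += float(sid_loss(
                        Tensor(means[i, r:r + 1]), means[j, r:r + 1]).data)
                n_pairs += 1
        unc = np.repeat((pair_sid / n_pairs)[:, None], means.shape[2], axis=1)
        return UncertaintyBundle(means.mean(axis=0), unc, "spectra_roundrobin")

    raise ValueError(f"unknown uncertainty method {method!r}")


# ---------------------------------------------------------------------------
# regression calibration
def _check_cal(bundle: UncertaintyBundle, targets: np.ndarray) -> np.ndarray:
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if targets.shape[0] < MIN_CALIBRATION_POINTS:
        raise ValueError(
            f"calibration needs >= {MIN_CALIBRATION_POINTS} points, "
            f"got {targets.shape[0]}")
    return targets


def calibrate_regression(bundle: UncertaintyBundle, targets: np.ndarray,
                         method: str = "z_scaling") -> UncertaintyBundle:
    """Rescale regression uncertainties on a held-out calibration set.

    - ``z_scaling``: one multiplicative variance factor making the
      standardized residuals unit-variance (the NLL-optimal scalar).
    - ``t_scaling``: Student-t scale fitted to standardized residuals
      (df = n - 1), converted to a variance factor.
    - ``crude``: stores the empirical distribution of standardized
      residuals; the variance is scaled by its second moment and
      intervals use its quantiles.
    - ``mve_weighting``: reweights the member variance estimates of an
      MVE ensemble by minimizing held-out Gaussian NLL over softmax
      weights.
    """
    targets = _check_cal(bundle, targets)
    resid = targets - bundle.mean
    std_resid = resid / np.sqrt(bundle.unc)

    if method == "z_scaling":
        factor = float(np.mean(std_resid ** 2))
        return bundle.with_unc(bundle.unc * factor,
                               {"method": "z_scaling", "factor": factor})

    if method == "t_scaling":
        df = max(std_resid.size - 1, 3)
        _, loc, scale = stats.t.fit(std_resid.ravel(), f0=df, floc=0.0)
        factor = float(scale ** 2 * df / (df - 2))
        return bundle.with_unc(bundle.unc * factor,
                               {"method": "t_scaling", "df": df,
                                "scale": float(scale), "factor": factor})

    if method == "crude":
        pool = np.sort(std_resid.ravel())
        factor = float(np.mean(pool ** 2))
        return bundle.with_unc(bundle.unc * factor,
                               {"method": "crude", "factor": factor,
                                "residual_pool": pool.tolist()})

    if method == "mve_weighting":
        if bundle.member_vars is None:
            raise ValueError("mve_weighting needs per-member variance "
                             "estimates (an MVE ensemble)")
        mv = bundle.member_vars  # (m, n, t)
        from scipy.optimize import minimize

        def nll(theta):
            w = np.exp(theta - theta.max())
            w /= w.sum()
            var = np.tensordot(w, mv, axes=1)
            return float(np.mean(0.5 * (np.log(2 * np.pi * var)
                                        + resid ** 2 / var)))

        res = minimize(nll, np.zeros(mv.shape[0]), method="Nelder-Mead")
        w = np.exp(res.x - res.x.max())
        w /= w.sum()
        var = np.tensordot(w, mv, axes=1)
        return bundle.with_unc(var, {"method": "mve_weighting",
                                     "weights": w.tolist()})

    raise ValueError(f"unknown regression calibration {method!r}")


def interval(bundle: UncertaintyBundle, level: float = 0.9
             ) -> tuple[np.ndarray, np.ndarray]:
    """Central predictive interval at ``level`` using the calibrated
    uncertainty; CRUDE uses its stored empirical quantiles."""
    cal = bundle.calibration or {}
    if cal.get("method") == "crude":
        pool = np.asarray(cal["residual_pool"])
        factor = cal.get("factor", 1.0)
        base = np.sqrt(bundle.unc / factor)  # un-scaled sigma
        lo_q = np.quantile(pool, (1 - level) / 2, method="linear")
        hi_q = np.quantile(pool, (1 + level) / 2, method="linear")
        return bundle.mean + lo_q * base, bundle.mean + hi_q * base
    if cal.get("method") == "t_scaling":
        df = cal["df"]
        half = stats.t.ppf((1 + level) / 2, df) * cal["scale"] * np.sqrt(
            bundle.unc / cal["factor"])
        return bundle.mean - half, bundle.mean + half
    z = stats.norm.ppf((1 + level) / 2)
    half = z * np.sqrt(bundle.unc)
    return bundle.mean - half, bundle.mean + half


# ---------------------------------------------------------------------------
# classification calibration
def calibrate_classification(bundle: UncertaintyBundle, targets: np.ndarray,
                             method: str = "platt") -> UncertaintyBundle:
    """Monotone recalibration of binary probabilities.

    ``platt`` fits a single temperature on the logits by NLL; ``isotonic``
    fits a nondecreasing step function (sklearn).  Ranking is preserved.
    """
    targets = _check_cal(bundle, targets)
    y = targets.ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("classification calibration needs both classes")
    p = np.clip(bundle.mean.ravel(), 1e-8, 1 - 1e-8)
    logit = np.log(p / (1 - p))

    if method == "platt":
        from scipy.optimize import minimize_scalar

        def nll(a):
            from scipy.special import expit
            q = np.clip(expit(a * logit), 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(q) + (1 - y) * np.log(1 - q))

        res = minimize_scalar(nll, bounds=(1e-3, 1e3), method="bounded")
        a = float(res.x)
        cal = {"method": "platt", "temperature": a}
        return _dc_replace(bundle, calibration=cal)

    if method == "isotonic":
        from sklearn.isotonic import IsotonicRegression
        iso = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
        iso.fit(p, y)
        cal = {"method": "isotonic",
               "x": iso.X_thresholds_.tolist(), "y": iso.y_thresholds_.tolist()}
        return _dc_replace(bundle, calibration=cal)

    raise ValueError(f"unknown classification calibration {method!r}")


def apply_classification_calibration(bundle: UncertaintyBundle,
                                     probs: np.ndarray) -> np.ndarray:
    """Map raw probabilities through the fitted calibration."""
    cal = bundle.calibration or {}
    p = np.clip(np.asarray(probs, dtype=np.float64), 1e-8, 1 - 1e-8)
    if cal.get("method") == "platt":
        a = cal["temperature"]
        return 1.0 / (1.0 + np.exp(-a * np.log(p / (1 - p))))
    if cal.get("method") == "isotonic":
        return np.interp(p, cal["x"], cal["y"])
    return p


# ---------------------------------------------------------------------------
# evaluation of uncertainty quality
def evaluate_uncertainty(bundle: UncertaintyBundle, targets: np.ndarray,
                         metric: str, n_bins: int = DEFAULT_ENCE_BINS) -> float:
    """Score the uncertainty estimates against realized errors.

    ``nll``: Gaussian NLL with the bundle variances.  ``spearman``: rank
    correlation between |error| and uncertainty.  ``ence``: mean over
    equal-count bins of |RMSE - RMV| / RMV.  ``miscalibration_area``: area
    between the empirical central-interval coverage curve and the ideal
    diagonal.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    resid = (targets - bundle.mean).ravel()
    unc = bundle.unc.ravel()

    if metric == "nll":
        return float(np.mean(0.5 * (np.log(2 * np.pi * unc)
                                    + resid ** 2 / unc)))
    if metric == "spearman":
        if np.ptp(unc) == 0:
            raise UndefinedMetricError(
                "Spearman correlation is undefined for constant uncertainties")
        rho = stats.spearmanr(np.abs(resid), unc).statistic
        return float(rho)
    if metric == "ence":
        order = np.argsort(unc)
        bins = np.array_split(order, n_bins)
        terms = []
        for b in bins:
            if len(b) == 0:
                continue
            rmv = np.sqrt(np.mean(unc[b]))
            rmse = np.sqrt(np.mean(resid[b] ** 2))
            terms.append(abs(rmse - rmv) / rmv)
        return float(np.mean(terms))
    if metric == "miscalibration_area":
        levels = np.linspace(0.01, 0.99, 99)
        z = stats.norm.ppf((1 + levels) / 2)
        half = np.sqrt(unc)[:, None] * z[None, :]
        covered = (np.abs(resid)[:, None] <= half).mean(axis=0)
        return float(np.trapezoid(np.abs(covered - levels), levels))
    raise ValueError(f"unknown uncertainty metric {metric!r}")


def coverage(bundle: UncertaintyBundle, targets: np.ndarray,
             level: float = 0.9) -> float:
    """Fraction of targets inside the central predictive interval."""
    lo, hi = interval(bundle, level)
    t = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    return float(((t >= lo) & (t <= hi)).mean())
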