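"""Training losses and evaluation metrics.

Training losses operate on autodiff tensors and return a scalar tensor
(mean over unmasked entries).  Targets and masks are plain NumPy arrays:
no gradient flows into them, and a zero mask entry provably contributes
zero gradient (it multiplies the per-entry loss term).

Regression: MSE, bounded MSE (inequality targets such as ``">5.0"`` incur
no loss once satisfied), Gaussian NLL for mean-variance estimation, and
the evidential normal-inverse-gamma NLL with an evidence regularizer.
Classification: binary cross entropy, multiclass cross entropy, a
differentiable soft Matthews correlation surrogate, and the Dirichlet
evidential loss.  Spectra: spectral information divergence (a symmetric
KL-style divergence over normalized spectra) and the 1-D first-order
Wasserstein (earthmover's) distance between their cumulative sums.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .autodiff import Tensor

SID_THRESHOLD = 1e-8
EVIDENTIAL_LAMBDA = 0.2
_EPS = 1e-12


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined on the given data."""


# ---------------------------------------------------------------------------
# target parsing
def parse_bounded_target(cell, row: int | None = None) -> tuple[float, str]:
    """Parse a CSV cell into (value, relation); relation in {"=", "<", ">"}."""
    where = "" if row is None else f" (row {row})"
    if isinstance(cell, (int, float, np.floating)):
        return float(cell), "="
    s = str(cell).strip()
    rel = "="
    if s[:1] in ("<", ">"):
        rel, s = s[0], s[1:]
    elif s[:1] == "=":
        s = s[1:]
    try:
        return float(s), rel
    except ValueError:
        raise ValueError(f"malformed inequality target {cell!r}{where}") from None


def _masked_mean(per_entry: Tensor, mask: np.ndarray | None) -> Tensor:
    if mask is None:
        return per_entry.mean()
    mask = np.asarray(mask, dtype=np.float64)
    denom = max(mask.sum(), 1.0)
    return (per_entry * Tensor(mask)).sum() * (1.0 / denom)


# ---------------------------------------------------------------------------
# regression
def mse_loss(pred: Tensor, target: np.ndarray,
             mask: np.ndarray | None = None) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    return _masked_mean(diff * diff, mask)


def bounded_mse(pred: Tensor, values: np.ndarray, relations: np.ndarray,
                mask: np.ndarray | None = None) -> Tensor:
    """Squared error, zeroed where an inequality target is already satisfied.

    ``relations`` holds "=", "<" or ">" per entry; ">5" means the true value
    exceeds 5, so any prediction above 5 is penalty-free.
    """
    values = np.asarray(values, dtype=np.float64)
    relations = np.asarray(relations)
    p = pred.data
    active = np.where(relations == ">", p < values,
                      np.where(relations == "<", p > values, True))
    diff = pred - Tensor(values)
    return _masked_mean(diff * diff * Tensor(active.astype(np.float64)), mask)


def mve_nll(pred_mean: Tensor, pred_var: Tensor, target: np.ndarray,
            mask: np.ndarray | None = None) -> Tensor:
    """Gaussian negative log-likelihood 0.5[log(2 pi v) + (y - mu)^2 / v]."""
    if np.any(pred_var.data <= 0):
        raise ValueError("mean-variance NLL requires strictly positive variance")
    y = Tensor(np.asarray(target, dtype=np.float64))
    resid = pred_mean - y
    per = 0.5 * ((pred_var * (2.0 * np.pi)).log() + resid * resid / pred_var)
    return _masked_mean(per, mask)


def evidential_regression_loss(gamma: Tensor, nu: Tensor, alpha: Tensor,
                               beta: Tensor, target: np.ndarray,
                               lam: float = EVIDENTIAL_LAMBDA,
                               mask: np.ndarray | None = None) -> Tensor:
    """Normal-inverse-gamma NLL plus ``lam`` x evidence-scaled |error|.

    The NIG head yields aleatoric variance beta/(alpha-1) and epistemic
    variance beta/(nu (alpha-1)); the regularizer shrinks evidence
    (2 nu + alpha) on points with large error.
    """
    if np.any(nu.data <= 0) or np.any(beta.data <= 0) or np.any(alpha.data <= 1):
        raise ValueError("evidential parameters require nu>0, beta>0, alpha>1")
    y = Tensor(np.asarray(target, dtype=np.float64))
    resid = gamma - y
    omega = 2.0 * beta * (1.0 + nu)
    nll = (0.5 * (Tensor(np.pi) / nu).log()
           - alpha * omega.log()
           + (alpha + 0.5) * (resid * resid * nu + omega).log()
           + alpha.lgamma() - (alpha + 0.5).lgamma())
    reg = resid.abs() * (2.0 * nu + alpha)
    return _masked_mean(nll + lam * reg, mask)


def evidential_variances(nu: np.ndarray, alpha: np.ndarray,
                         beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(aleatoric, epistemic) variances from NIG head parameters."""
    aleatoric = beta / (alpha - 1.0)
    epistemic = beta / (nu * (alpha - 1.0))
    return aleatoric, epistemic


# ---------------------------------------------------------------------------
# classification
def bce_loss(prob: Tensor, target: np.ndarray,
             mask: np.ndarray | None = None) -> Tensor:
    y = np.asarray(target, dtype=np.float64)
    p = prob.clamp_min(_EPS)
    q = (1.0 - prob).clamp_min(_EPS)
    per = -(Tensor(y) * p.log() + Tensor(1.0 - y) * q.log())
    return _masked_mean(per, mask)


def cross_entropy_loss(probs: Tensor, target: np.ndarray, n_classes: int,
                       mask: np.ndarray | None = None) -> Tensor:
    """Multiclass CE; ``probs`` is (n, n_tasks * n_classes) simplex blocks,
    ``target`` integer class labels (n, n_tasks)."""
    target = np.atleast_2d(np.asarray(target, dtype=np.intp))
    n, n_tasks = target.shape
    rows = np.repeat(np.arange(n), n_tasks)
    cols = (np.tile(np.arange(n_tasks), n) * n_classes
            + target[rows, np.tile(np.arange(n_tasks), n)])
    picked = probs[(rows, cols)].reshape(n, n_tasks)
    return _masked_mean(-picked.clamp_min(_EPS).log(), mask)


def soft_mcc_loss(prob: Tensor, target: np.ndarray,
                  mask: np.ndarray | None = None) -> Tensor:
    """1 - soft Matthews correlation for binary tasks.

    Confusion counts are accumulated in expectation from the predicted
    probabilities, making the surrogate differentiable; hard 0/1
    predictions recover the usual MCC.
    """
    y = np.asarray(target, dtype=np.float64).reshape(prob.data.shape)
    w = (np.ones_like(y) if mask is None
         else np.asarray(mask, dtype=np.float64).reshape(y.shape))
    tp = (prob * Tensor(y * w)).sum()
    fp = (prob * Tensor((1.0 - y) * w)).sum()
    fn = ((1.0 - prob) * Tensor(y * w)).sum()
    tn = ((1.0 - prob) * Tensor((1.0 - y) * w)).sum()
    num = tp * tn - fp * fn
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) + _EPS) ** 0.5
    return 1.0 - num / den


def multiclass_mcc_loss(probs: Tensor, target: np.ndarray, n_classes: int,
                        mask: np.ndarray | None = None) -> Tensor:
    """1 - soft multiclass Matthews correlation (Gorodkin's R_K) from the
    expected confusion matrix; averaged over tasks."""
    target = np.atleast_2d(np.asarray(target, dtype=np.intp))
    n, n_tasks = target.shape
    w = (np.ones((n, n_tasks)) if mask is None
         else np.asarray(mask, dtype=np.float64).reshape(n, n_tasks))
    total = None
    for t in range(n_tasks):
        block = probs[:, t * n_classes:(t + 1) * n_classes]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), target[:, t]] = 1.0
        onehot *= w[:, t:t + 1]
        block = block * Tensor(w[:, t:t + 1])
        C = Tensor(onehot.T) @ block          # soft confusion counts
        s = C.sum()
        c = sum((C[(k, k)] for k in range(n_classes)), Tensor(0.0))
        pk = C.sum(axis=0)                    # predicted-class totals
        tk = C.sum(axis=1)                    # true-class totals
        num = c * s - (pk * tk).sum()
        den = (((s * s - (pk * pk).sum()) * (s * s - (tk * tk).sum()))
               + _EPS) ** 0.5
        mcc = num / den
        total = mcc if total is None else total + mcc
    return 1.0 - total * (1.0 / n_tasks)


def dirichlet_loss(alphas: Tensor, target: np.ndarray,
                   lam: float = 0.1,
                   mask: np.ndarray | None = None) -> Tensor:
    """Evidential binary classification: Bayes-risk squared error of the
    Dirichlet mean plus a KL(Dir(alpha~) || Dir(1)) regularizer on the
    misleading evidence.  ``alphas`` is (n, 2 * n_tasks): per task, the
    concentrations for the negative then positive class."""
    y = np.asarray(target, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    n, n_tasks = y.shape
    total = None
    for t in range(n_tasks):
        a = alphas[:, 2 * t:2 * t + 2]
        S = a.sum(axis=1, keepdims=True)
        p = a / S
        onehot = np.stack([1.0 - y[:, t], y[:, t]], axis=1)
        err = ((Tensor(onehot) - p) ** 2 + p * (1.0 - p) / (S + 1.0)).sum(
            axis=1, keepdims=True)
        # misleading evidence: alpha~ = y + (1 - y) * alpha
        a_t = Tensor(onehot) + Tensor(1.0 - onehot) * a
        S_t = a_t.sum(axis=1, keepdims=True)
        kl = (S_t.lgamma() - a_t.lgamma().sum(axis=1, keepdims=True)
              - Tensor(gammaln(2.0))
              + ((a_t - 1.0) * (a_t.digamma() - S_t.digamma())).sum(
                  axis=1, keepdims=True))
        per = err + lam * kl
        m = None if mask is None else np.asarray(mask)[:, t:t + 1]
        term = _masked_mean(per, m)
        total = term if total is None else total + term
    return total * (1.0 / n_tasks)


def classification_losses(pred: Tensor, target: np.ndarray, kind: str,
                          n_classes: int = 2,
                          mask: np.ndarray | None = None) -> Tensor:
    """Dispatch by loss name; ``kind``/task compatibility is validated."""
    if kind == "bce":
        return bce_loss(pred, target, mask)
    if kind == "cross_entropy":
        return cross_entropy_loss(pred, target, n_classes, mask)
    if kind == "mcc":
        if n_classes == 2:
            return soft_mcc_loss(pred, target, mask)
        return multiclass_mcc_loss(pred, target, n_classes, mask)
    if kind == "dirichlet":
        return dirichlet_loss(pred, target, mask=mask)
    raise ValueError(f"unknown classification loss {kind!r}")


# ---------------------------------------------------------------------------
# spectra
def _normalize_spectrum(x: Tensor, mask: np.ndarray,
                        threshold: float) -> Tensor:
    xm = x * Tensor(mask)
    norm = xm / xm.sum(axis=1, keepdims=True)
    return norm.clamp_min(threshold)


def _check_spectra(pred: Tensor, target: np.ndarray,
                   mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if mask is None:
        mask = ~np.isnan(target)
    mask = np.asarray(mask, dtype=np.float64).reshape(target.shape)
    if np.any(mask.sum(axis=1) == 0):
        raise ValueError("a spectrum with every bin masked has no valid loss")
    if np.any(pred.data < 0) or np.any(np.nan_to_num(target) < 0):
        raise ValueError("spectra must be nonnegative")
    return np.nan_to_num(target), mask


def sid_loss(pred: Tensor, target: np.ndarray,
             mask: np.ndarray | None = None,
             threshold: float = SID_THRESHOLD) -> Tensor:
    """Spectral information divergence between normalized spectra.

    Both spectra are renormalized to unit sum over valid bins and floored
    at ``threshold``; the loss is sum_b p ln(p/q) + q ln(q/p), averaged
    over rows.  Symmetric, nonnegative, zero iff the normalized spectra
    coincide.
    """
    target, mask = _check_spectra(pred, target, mask)
    p = _normalize_spectrum(pred, mask, threshold)
    qm = target * mask
    q = qm / qm.sum(axis=1, keepdims=True)
    q = np.maximum(q, threshold)
    terms = p * (p / Tensor(q)).log() + Tensor(q) * (Tensor(q) / p).log()
    return (terms * Tensor(mask)).sum(axis=1).mean()


def wasserstein_loss(pred: Tensor, target: np.ndarray,
                     mask: np.ndarray | None = None,
                     threshold: float = SID_THRESHOLD) -> Tensor:
    """First-order Wasserstein distance between normalized 1-D spectra:
    the L1 distance between their cumulative sums, in bin-width units.
    Masked bins carry no mass and are excluded from the sum."""
    target, mask = _check_spectra(pred, target, mask)
    n_bins = target.shape[1]
    p = _normalize_spectrum(pred, mask, threshold) * Tensor(mask)
    qm = target * mask
    q = qm / qm.sum(axis=1, keepdims=True)
    tri = np.tril(np.ones((n_bins, n_bins))).T  # cumulative-sum operator
    cdf_p = p @ Tensor(tri)
    cdf_q = np.cumsum(q, axis=1)
    return ((cdf_p - Tensor(cdf_q)).abs() * Tensor(mask)).sum(axis=1).mean()


# ---------------------------------------------------------------------------
# evaluation metrics (numpy in, float out; never used for gradients)
EVAL_METRICS = ("rmse", "mae", "r2", "auroc", "auprc", "accuracy", "mcc",
                "cross_entropy", "sid", "wasserstein")


def evaluation_metrics(preds: np.ndarray, targets: np.ndarray, metric: str,
                       mask: np.ndarray | None = None, **kwargs) -> float:
    """Evaluation-only scores.  Raises :class:`UndefinedMetricError` when a
    metric is undefined (e.g. AUROC with a single observed class)."""
    preds = np.asarray(preds, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if metric in ("sid", "wasserstein"):
        fn = sid_loss if metric == "sid" else wasserstein_loss
        return float(fn(Tensor(preds), targets, mask=mask, **kwargs).data)
    p = preds.ravel()
    t = targets.ravel()
    if mask is not None:
        keep = np.asarray(mask, dtype=bool).ravel()
        p, t = p[keep], t[keep]
    else:
        keep = ~np.isnan(t)
        p, t = p[keep], t[keep]
    if len(t) == 0:
        raise UndefinedMetricError("no unmasked targets to evaluate")
    if metric == "rmse":
        return float(np.sqrt(np.mean((p - t) ** 2)))
    if metric == "mae":
        return float(np.mean(np.abs(p - t)))
    if metric == "r2":
        from sklearn.metrics import r2_score
        return float(r2_score(t, p))
    if metric == "cross_entropy":
        return float(-np.mean(np.log(np.clip(
            np.where(t > 0.5, p, 1.0 - p), _EPS, None))))
    if metric in ("auroc", "auprc"):
        from sklearn.metrics import roc_auc_score, average_precision_score
        if len(np.unique(t)) < 2:
            raise UndefinedMetricError(
                f"{metric} is undefined with a single observed class")
        fn = roc_auc_score if metric == "auroc" else average_precision_score
        return float(fn(t, p))
    if metric == "accuracy":
        return float(np.mean((p > 0.5) == (t > 0.5)))
    if metric == "mcc":
        from sklearn.metrics import matthews_corrcoef
        return float(matthews_corrcoef(t > 0.5, p > 0.5))
    raise ValueError(f"unknown metric {metric!r}")
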