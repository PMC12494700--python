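"""Volumetric loss, differentiable surrogate, and the optimization loop.

The loss rewards voxelwise agreement between the binary prediction and the
ligand-derived ground truth while down-weighting the (vastly more numerous)
background voxels through the hyperparameter ``k``:

    L = (|pred & truth| + k |~pred & ~truth|) / (|truth| + k |~truth|)

L lives in [0, 1] and is to be *maximized*; k = 0 reduces it to recall and
k = 1 to plain accuracy.  The hard threshold inside the model is not
differentiable, so optimization runs through a temperature-annealed logistic
surrogate; all reported losses are recomputed with the hard threshold.

Gradients are assembled analytically for the combination weights, the
threshold, and (in the ablation variants) the free kernel taps; the kernel
shape parameters sigma_i enter through the sampled kernel and are
differentiated by central finite differences on the kernel alone.  Updates
use a hand-rolled Adam with per-example (batch size 1) steps and seeded
shuffling, which keeps runs bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate
from scipy.special import expit

from .channels import ChannelStack, N_CHANNELS, TruthMask
from .errors import (
    ConfigError,
    DegenerateDenominatorError,
    TrainingDivergedError,
)
from .kernels import SIGMA_FLOOR_FACTOR, build_kernel, DEFAULT_FAMILIES
from .model import (
    FreeKernelParams,
    GENEOParams,
    apply_geneo,
    combined_field,
    hard_threshold,
    normalize_output,
    VARIANTS,
)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def volumetric_loss(psi_hat: np.ndarray, tau: np.ndarray, k: float) -> float:
    """Eq.-style volumetric matching loss on binary fields, in [0, 1]."""
    if not (0.0 <= k <= 1.0):
        raise ValueError("k must lie in [0, 1]")
    psi_hat = np.asarray(psi_hat).astype(bool)
    tau = np.asarray(tau).astype(bool)
    if psi_hat.shape != tau.shape:
        raise ValueError("prediction and truth must share a grid")
    n_tau = int(tau.sum())
    n_not_tau = tau.size - n_tau
    denom = n_tau + k * n_not_tau
    if denom == 0:
        raise DegenerateDenominatorError("empty truth with k = 0")
    inter = int((psi_hat & tau).sum())
    co_absent = int((~psi_hat & ~tau).sum())
    return (inter + k * co_absent) / denom


def soft_binarize(psi: np.ndarray, theta: float, temperature: float) -> np.ndarray:
    """Logistic relaxation of the hard threshold; -> hard as T -> 0."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return expit((psi - theta) / temperature)


def soft_volumetric_loss(soft_pred: np.ndarray, tau: np.ndarray, k: float) -> float:
    """Loss with the binary prediction replaced by its soft relaxation."""
    tau = np.asarray(tau).astype(float)
    n_tau = tau.sum()
    denom = n_tau + k * (tau.size - n_tau)
    if denom == 0:
        raise DegenerateDenominatorError("empty truth with k = 0")
    num = (soft_pred * tau).sum() + k * ((1.0 - soft_pred) * (1.0 - tau)).sum()
    return float(num / denom)


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass
class TrainingExample:
    stack: ChannelStack
    truth: TruthMask
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.truth.values.shape != self.stack.grid.dims:
            raise ValueError("channel stack and truth mask must share a grid")


@dataclass
class TrainingConfig:
    k: float = 0.02
    epochs: int = 50
    learning_rate: float = 0.01
    seed: int = 0
    temp_start: float = 0.1
    temp_end: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    init_sigma: float = 2.0
    init_theta: float = 0.5
    families: tuple[str, ...] = DEFAULT_FAMILIES
    truncation_factor: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.k <= 1.0):
            raise ConfigError("k must lie in [0, 1]")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning rate must be positive")
        if self.temp_start <= 0 or self.temp_end <= 0:
            raise ConfigError("temperatures must be positive")
        if not (0.0 < self.init_theta < 1.0):
            raise ConfigError("init_theta must lie strictly inside (0, 1)")

    def temperature(self, epoch: int) -> float:
        if self.epochs == 1:
            return self.temp_start
        frac = epoch / (self.epochs - 1)
        return self.temp_start + (self.temp_end - self.temp_start) * frac


@dataclass
class FitResult:
    params: GENEOParams | FreeKernelParams
    train_loss: list[float]
    val_loss: list[float] | None
    seed: int
    config: TrainingConfig
    variant: str = "E-NE"


# ---------------------------------------------------------------------------
# Reparameterizations (keep constraints satisfied by construction)
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


def _softmax(a):
    e = np.exp(a - a.max())
    return e / e.sum()


def _logit(p):
    return np.log(p / (1.0 - p))


class _Adam:
    def __init__(self, shapes: dict, lr: float, b1: float, b2: float, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        """Gradient-ascent Adam update in place."""
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            params[key] = params[key] + self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Gradient machinery
# ---------------------------------------------------------------------------

_SIGMA_FD_STEP = 1e-3


def sigma_cap_for(dims, spacing: float, truncation_factor: float) -> float:
    """Largest sigma whose truncated kernel still fits a grid of ``dims``
    (kernel radius ceil(truncation_factor * sigma / spacing) must not
    exceed half the smallest grid edge)."""
    max_radius = (min(dims) - 1) // 2
    return max_radius * spacing / truncation_factor


def _forward_soft(psis, alphas, theta, temp, mask, tau, k):
    """Soft loss + the shared upstream gradient pieces.

    The min-max normalization is differentiated exactly: the masked argmin
    and argmax voxels carry the gradient of the rescaling bounds (first
    occurrence on ties, a valid subgradient).
    """
    combined = np.tensordot(alphas, psis, axes=(0, 0))
    flat_mask_idx = np.flatnonzero(mask.ravel())
    vals = combined.ravel()[flat_mask_idx]
    i_min = int(flat_mask_idx[np.argmin(vals)])
    i_max = int(flat_mask_idx[np.argmax(vals)])
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo
    degenerate = span < 1e-300
    if degenerate:
        z = np.full_like(combined, 0.5)
        z_raw = z
        dz_dc = np.zeros_like(combined)
    else:
        z_raw = (combined - lo) / span
        z = np.clip(z_raw, 0.0, 1.0)
        dz_dc = np.where((z_raw >= 0.0) & (z_raw <= 1.0), 1.0 / span, 0.0)
    s = expit((z - theta) / temp)
    tau_f = tau.astype(float)
    n_tau = tau_f.sum()
    denom = n_tau + k * (tau_f.size - n_tau)
    loss = float(((s * tau_f).sum()
                  + k * ((1.0 - s) * (1.0 - tau_f)).sum()) / denom)
    g_s = (tau_f - k * (1.0 - tau_f)) / denom          # dL/ds
    s_prime = s * (1.0 - s) / temp
    g_z = g_s * s_prime                                 # dL/dz
    g_c = g_z * dz_dc                                   # dL/dcombined, local
    if not degenerate:
        # bound terms: dz_x/dlo = (z_x - 1)/span, dz_x/dhi = -z_x/span,
        # restricted to the unclipped voxels
        active = (z_raw >= 0.0) & (z_raw <= 1.0)
        gz_active = np.where(active, g_z, 0.0)
        d_lo = float((gz_active * (z_raw - 1.0)).sum()) / span
        d_hi = float(-(gz_active * z_raw).sum()) / span
        g_c = g_c.copy()
        g_c.ravel()[i_min] += d_lo
        g_c.ravel()[i_max] += d_hi
    g_theta = float(-(g_s * s_prime).sum())             # dL/dtheta
    return loss, g_c, g_theta


def _ene_gradients(stack, tau, raw, config, temp, sigma_cap=None):
    """Soft loss and gradients w.r.t. the raw (unconstrained) parameters of
    the equivariant variant.

    Sigmas are projected onto [floor, sigma_cap]; at the cap the gradient
    is zero (projected gradient step)."""
    spacing = stack.grid.spacing
    floor = SIGMA_FLOOR_FACTOR * spacing
    if sigma_cap is None:
        sigma_cap = sigma_cap_for(stack.fields.shape[1:], spacing,
                                  config.truncation_factor)
    sigmas = np.minimum(floor + _softplus(raw["u"]), sigma_cap)
    alphas = _softmax(raw["a"])
    theta = float(expit(raw["t"]))

    kernels = [build_kernel(f, s, spacing, config.truncation_factor)
               for f, s in zip(config.families, sigmas)]
    psis = np.stack([apply_geneo(stack.fields[i], kernels[i].taps)
                     for i in range(N_CHANNELS)])
    loss, g_c, g_theta = _forward_soft(psis, alphas, theta, temp,
                                       stack.empty_space_mask, tau, config.k)

    g_alpha = np.array([(g_c * psis[i]).sum() for i in range(N_CHANNELS)])
    g_a = alphas * (g_alpha - float(alphas @ g_alpha))
    g_t = g_theta * theta * (1.0 - theta)

    g_u = np.zeros(N_CHANNELS)
    h = _SIGMA_FD_STEP
    for i in range(N_CHANNELS):
        if alphas[i] < 1e-10:
            continue   # no influence on the loss at this point
        up = min(sigmas[i] + h, sigma_cap)
        dn = max(sigmas[i] - h, floor)
        step = up - dn
        if step <= 0:
            continue   # pinned between floor and cap
        k_plus = build_kernel(config.families[i], up, spacing,
                              config.truncation_factor).taps
        k_minus = build_kernel(config.families[i], dn, spacing,
                               config.truncation_factor).taps
        if k_plus.shape != k_minus.shape:
            pad = [(a - b) // 2 for a, b in zip(k_plus.shape, k_minus.shape)]
            k_minus = np.pad(k_minus, [(p, p) for p in pad])
        dpsi = apply_geneo(stack.fields[i], (k_plus - k_minus) / step)
        g_sigma = alphas[i] * float((g_c * dpsi).sum())
        g_u[i] = g_sigma * expit(raw["u"][i])

    return loss, {"u": g_u, "a": g_a, "t": np.array(g_t)}


def _kernel_gradient(g_c: np.ndarray, phi: np.ndarray, shape) -> np.ndarray:
    """d(loss)/d(taps) for psi = phi * K: cross-correlation of the upstream
    gradient with the channel, sampled on the kernel support."""
    full = correlate(g_c, phi, mode="full", method="auto")
    center = [n - 1 for n in phi.shape]
    radius = [s // 2 for s in shape]
    sl = tuple(slice(c - r, c + r + 1) for c, r in zip(center, radius))
    return full[sl]


def _free_gradients(stack, tau, raw, config, temp, l1_normalized):
    alphas = _softmax(raw["a"])
    theta = float(expit(raw["t"]))
    taps_raw = [raw[f"w{i}"] for i in range(N_CHANNELS)]
    if l1_normalized:
        norms = [np.abs(w).sum() for w in taps_raw]
        taps = [w / n for w, n in zip(taps_raw, norms)]
    else:
        taps = taps_raw
    psis = np.stack([apply_geneo(stack.fields[i], taps[i])
                     for i in range(N_CHANNELS)])
    loss, g_c, g_theta = _forward_soft(psis, alphas, theta, temp,
                                       stack.empty_space_mask, tau, config.k)

    g_alpha = np.array([(g_c * psis[i]).sum() for i in range(N_CHANNELS)])
    grads = {"a": alphas * (g_alpha - float(alphas @ g_alpha)),
             "t": np.array(g_theta * theta * (1.0 - theta))}
    for i in range(N_CHANNELS):
        if alphas[i] < 1e-10:
            grads[f"w{i}"] = np.zeros_like(taps_raw[i])
            continue
        g_k = alphas[i] * _kernel_gradient(g_c, stack.fields[i], taps[i].shape)
        if l1_normalized:
            w = taps_raw[i]
            g_k = (g_k - np.sign(w) * float((g_k * taps[i]).sum())) / norms[i]
        grads[f"w{i}"] = g_k
    return loss, grads


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _init_raw(variant: str, config: TrainingConfig, spacing: float,
              sigma_cap: float = np.inf) -> dict:
    floor = SIGMA_FLOOR_FACTOR * spacing
    init_sigma = min(config.init_sigma, sigma_cap)
    raw = {"a": np.zeros(N_CHANNELS),
           "t": np.array(_logit(config.init_theta))}
    if variant == "E-NE":
        raw["u"] = np.full(N_CHANNELS, _inv_softplus(init_sigma - floor))
    else:
        for i in range(N_CHANNELS):
            spec = build_kernel(config.families[i], init_sigma, spacing,
                                config.truncation_factor)
            raw[f"w{i}"] = spec.taps.copy()
    return raw


def _materialize(variant: str, raw: dict, config: TrainingConfig,
                 spacing: float, sigma_cap: float = np.inf):
    floor = SIGMA_FLOOR_FACTOR * spacing
    alphas = _softmax(raw["a"])
    theta = float(expit(raw["t"]))
    if variant == "E-NE":
        return GENEOParams(sigmas=np.minimum(floor + _softplus(raw["u"]),
                                             sigma_cap), alphas=alphas,
                           theta=theta, families=config.families,
                           spacing=spacing,
                           truncation_factor=config.truncation_factor)
    return FreeKernelParams(taps=[raw[f"w{i}"].copy() for i in range(N_CHANNELS)],
                            alphas=alphas, theta=theta,
                            l1_normalized=(variant == "NE-NE"), spacing=spacing)


def hard_loss(params, example: TrainingExample, k: float) -> float:
    """Hard-threshold loss of a parameter set on one example."""
    combined = combined_field(example.stack, params)
    psi = normalize_output(combined, example.stack.empty_space_mask)
    psi_hat = hard_threshold(psi, params.theta, example.stack.empty_space_mask)
    return volumetric_loss(psi_hat, example.truth.values, k)


def mean_hard_loss(params, examples, k: float) -> float:
    return float(np.mean([hard_loss(params, ex, k) for ex in examples]))


def fit(examples: list[TrainingExample], config: TrainingConfig | None = None,
        variant: str = "E-NE",
        val_examples: list[TrainingExample] | None = None) -> FitResult:
    """Maximize the mean soft surrogate loss with per-example Adam steps.

    Per-epoch bookkeeping records the mean hard-threshold loss on the
    training (and optional held-out) examples.  Fully deterministic given
    the config seed.
    """
    if config is None:
        config = TrainingConfig()
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    if not examples:
        raise ConfigError("need at least one training example")
    spacing = examples[0].stack.grid.spacing
    cap = min(sigma_cap_for(ex.stack.fields.shape[1:], spacing,
                            config.truncation_factor) for ex in examples)

    raw = _init_raw(variant, config, spacing, cap)
    adam = _Adam({k: np.shape(v) for k, v in raw.items()},
                 config.learning_rate, config.beta1, config.beta2,
                 config.adam_eps)
    rng = np.random.default_rng(config.seed)
    order = np.arange(len(examples))

    train_hist: list[float] = []
    val_hist: list[float] = []
    for epoch in range(config.epochs):
        temp = config.temperature(epoch)
        rng.shuffle(order)
        for idx in order:
            ex = examples[idx]
            if variant == "E-NE":
                _, grads = _ene_gradients(ex.stack, ex.truth.values, raw,
                                          config, temp, sigma_cap=cap)
            else:
                _, grads = _free_gradients(ex.stack, ex.truth.values, raw,
                                           config, temp,
                                           l1_normalized=(variant == "NE-NE"))
            for g in grads.values():
                if not np.all(np.isfinite(g)):
                    raise TrainingDivergedError(
                        f"non-finite gradient at epoch {epoch}")
            adam.step(raw, grads)
        params = _materialize(variant, raw, config, spacing, cap)
        train_hist.append(mean_hard_loss(params, examples, config.k))
        if val_examples:
            val_hist.append(mean_hard_loss(params, val_examples, config.k))

    return FitResult(params=_materialize(variant, raw, config, spacing, cap),
                     train_loss=train_hist,
                     val_loss=val_hist if val_examples else None,
                     seed=config.seed, config=config, variant=variant)


def multi_restart_select(train_sets: list[list[TrainingExample]],
                         validation_examples: list[TrainingExample],
                         config: TrainingConfig | None = None,
                         variant: str = "E-NE",
                         **model_kwargs) -> tuple[FitResult, list[float]]:
    """Train one model per training set and keep the one with the highest
    top-n ranking coefficient (H1 with one true pocket per example) on the
    validation examples; ties break toward the lower restart index.

    Returns the winning fit and the per-restart H1 values.
    """
    from .evaluation import h1_on_examples

    if not train_sets:
        raise ConfigError("need at least one training set")
    results = []
    scores = []
    for ts in train_sets:
        res = fit(ts, config, variant)
        results.append(res)
        scores.append(h1_on_examples(res.params, validation_examples,
                                     **model_kwargs))
    best = int(np.argmax(scores))   # argmax keeps the first maximum
    return results[best], scores
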