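"""Monte Carlo training and pruning of many identically configured networks.

Every network shares the dataset, architecture, hyper-parameters and
pruning schedule; only the weight-initialization seed differs (network k
uses ``base_seed + k``).  The analyses mirror the standard questions asked
of such an ensemble: where does each network break down (its *optimal
sparsity* — the sparsest level still under the loss threshold), how are
losses distributed per sparsity level, how uniformly do the layers prune,
and which inputs keep connections into the first hidden layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import Architecture, TrainConfig, evaluate, init_params, train
from .pruning import MaskSet, PruneSchedule, select_mask

__all__ = [
    "EnsembleConfig",
    "NetworkResult",
    "EnsembleResult",
    "run_ensemble",
    "optimal_sparsity",
    "layer_sparsity_table",
    "input_connectivity",
    "breakdown_summary",
    "residual_summary",
    "rollout_error",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Study conditions for one Monte Carlo pruning experiment."""

    n_networks: int = 12
    base_seed: int = 0
    arch: Architecture = field(default_factory=Architecture)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    schedule: PruneSchedule = field(default_factory=PruneSchedule)
    threshold: float = 1e-3
    scope: str = "global"
    retrain_config: TrainConfig | None = None  # per-sparsity retraining; defaults to train_config

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class NetworkResult:
    """Per-network outcome of train + sequential masked pruning."""

    seed: int
    pre_prune_loss: float                       # minimum monitored loss before pruning
    losses: dict[float, float]                  # sparsity -> thresholding loss
    per_layer_remaining: dict[float, list[int]]  # sparsity -> per-layer ones
    input_connectivity: dict[float, list[int]]  # sparsity -> layer-1 column counts
    failed: bool = False


@dataclass
class EnsembleResult:
    config: EnsembleConfig
    networks: list[NetworkResult]

    @property
    def n_failed(self) -> int:
        return sum(nr.failed for nr in self.networks)

    def ok_networks(self) -> list[NetworkResult]:
        return [nr for nr in self.networks if not nr.failed]

    def loss_matrix(self) -> tuple[list[float], np.ndarray]:
        """(sparsities, loss array (n_ok, n_sparsities))."""
        ss = list(self.config.schedule)
        ok = self.ok_networks()
        arr = np.array([[nr.losses[s] for s in ss] for nr in ok])
        return ss, arr

    def optimal_sparsities(self) -> list[float | None]:
        return [optimal_sparsity(nr.losses, self.config.threshold)
                for nr in self.ok_networks()]

    def summary(self) -> str:
        ss, arr = self.loss_matrix()
        pre = np.array([nr.pre_prune_loss for nr in self.ok_networks()])
        opts = self.optimal_sparsities()
        finite = [o for o in opts if o is not None]
        lines = [
            "Monte Carlo pruning ensemble",
            "============================",
            f"networks: {len(self.networks)} ({self.n_failed} failed)",
            f"threshold: {self.config.threshold:g}",
            f"median pre-prune loss: {np.median(pre):.3e}",
            f"networks with finite optimal sparsity: {len(finite)}/{len(opts)}",
        ]
        if finite:
            vals, counts = np.unique(finite, return_counts=True)
            mode = vals[np.argmax(counts)]
            lines.append(f"modal optimal sparsity: {mode:.0%} "
                         f"({counts.max()}/{len(opts)} networks)")
        lines.append("")
        lines.append("sparsity   median loss   n under threshold")
        for j, s in enumerate(ss):
            med = np.median(arr[:, j])
            under = int(np.sum(arr[:, j] < self.config.threshold))
            lines.append(f"  {s:5.0%}    {med:.3e}        {under}")
        return "\n".join(lines)


def run_ensemble(config: EnsembleConfig, train_inputs, train_targets,
                 threshold_inputs=None, threshold_targets=None,
                 val_inputs=None, val_targets=None) -> EnsembleResult:
    """Train and sequentially prune ``n_networks`` independent networks.

    The loss recorded per sparsity (and compared against the threshold) is
    evaluated on ``threshold_inputs/targets`` when given (a held-out test
    set), else on the training monitor set — the latter mirrors runs where
    cross-validation is omitted.
    """
    results: list[NetworkResult] = []
    use_test = threshold_inputs is not None
    if use_test:
        tX = np.asarray(threshold_inputs, float)
        tY = np.asarray(threshold_targets, float)
    for k in range(config.n_networks):
        seed = config.base_seed + k
        try:
            results.append(_run_one(config, seed, train_inputs, train_targets,
                                    tX if use_test else None,
                                    tY if use_test else None,
                                    val_inputs, val_targets))
        except (FloatingPointError, RuntimeError) as exc:
            logger.warning("network seed %d failed: %s", seed, exc)
            results.append(NetworkResult(seed=seed, pre_prune_loss=np.nan,
                                         losses={}, per_layer_remaining={},
                                         input_connectivity={}, failed=True))
    return EnsembleResult(config=config, networks=results)


def _run_one(config: EnsembleConfig, seed: int, X, Y, tX, tY,
             vX, vY) -> NetworkResult:
    params = init_params(config.arch, seed)
    tc = config.train_config.replace(seed=seed)
    rc = (config.retrain_config or config.train_config).replace(seed=seed)
    params, history = train(params, None, X, Y, vX, vY, tc)

    def threshold_loss(p, m):
        if tX is not None:
            return evaluate(p, m, tX, tY)
        k = min(np.asarray(X).shape[0], tc.monitor_subsample)
        return evaluate(p, m, np.asarray(X, float)[:k], np.asarray(Y, float)[:k])

    pre_loss = min(history.min_loss, threshold_loss(params, None)) \
        if tX is None else threshold_loss(params, None)

    losses: dict[float, float] = {}
    per_layer: dict[float, list[int]] = {}
    in_conn: dict[float, list[int]] = {}

    masks = MaskSet.ones_like(params)
    for s in config.schedule:
        masks = select_mask(params, s, scope=config.scope, current=masks)
        params, _ = train(params, masks, X, Y, vX, vY, rc)
        losses[s] = threshold_loss(params, masks)
        per_layer[s] = masks.per_layer_remaining()
        in_conn[s] = input_connectivity(masks.matrices[0]).tolist()
    return NetworkResult(seed=seed, pre_prune_loss=float(pre_loss),
                         losses=losses, per_layer_remaining=per_layer,
                         input_connectivity=in_conn)


def optimal_sparsity(losses: dict[float, float], threshold: float):
    """Largest schedule sparsity with loss strictly under the threshold."""
    if not losses:
        raise ValueError("empty loss mapping")
    under = [s for s, l in losses.items() if l < threshold]
    return max(under) if under else None


def layer_sparsity_table(masks: MaskSet):
    """Per-layer (remaining count, fraction remaining) as a DataFrame."""
    import pandas as pd

    rows = []
    for i, m in enumerate(masks.matrices, start=1):
        remaining = int(m.sum())
        rows.append({"layer": i, "remaining": remaining, "size": m.size,
                     "fraction_remaining": remaining / m.size})
    return pd.DataFrame(rows)


def aggregate_layer_table(per_layer_counts: list[list[int]],
                          layer_sizes: list[int]):
    """Mean/variance of per-layer remaining counts across an ensemble."""
    import pandas as pd

    arr = np.asarray(per_layer_counts, dtype=float)
    return pd.DataFrame({
        "layer": np.arange(1, arr.shape[1] + 1),
        "mean_remaining": arr.mean(axis=0),
        "variance": arr.var(axis=0),
        "fraction_remaining": arr.mean(axis=0) / np.asarray(layer_sizes, float),
    })


def input_connectivity(layer1_mask: np.ndarray) -> np.ndarray:
    """Remaining connections from each input into the first hidden layer.

    ``layer1_mask`` has shape (hidden_width, n_inputs); the count for input
    j is the number of ones in column j.
    """
    m = np.asarray(layer1_mask)
    if m.ndim != 2:
        raise ValueError("layer-1 mask must be 2-D")
    return np.count_nonzero(m, axis=0)


def breakdown_summary(result: EnsembleResult, threshold: float | None = None):
    """Histogram of optimal sparsities plus per-sparsity box-plot statistics.

    Returns a dict with keys ``histogram`` (sparsity -> network count),
    ``never_below`` (count), ``failed`` (count) and ``box_stats`` (list of
    per-sparsity dicts with median/quartiles/whiskers/outlier count).
    """
    thr = threshold if threshold is not None else result.config.threshold
    ss, arr = result.loss_matrix()
    opts = [optimal_sparsity(nr.losses, thr) for nr in result.ok_networks()]
    hist = {s: 0 for s in ss}
    never = 0
    for o in opts:
        if o is None:
            never += 1
        else:
            hist[o] += 1
    box = []
    for j, s in enumerate(ss):
        col = np.sort(arr[:, j])
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = col[(col >= lo) & (col <= hi)]
        box.append({
            "sparsity": s, "median": float(med), "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inliers.min()) if inliers.size else float(med),
            "whisker_high": float(inliers.max()) if inliers.size else float(med),
            "n_outliers": int(col.size - inliers.size),
        })
    return {"histogram": hist, "never_below": never,
            "failed": result.n_failed, "box_stats": box}


def residual_summary(params, masks, test_inputs, test_targets, scaler):
    """Per-output residual statistics (actual - prediction) in unscaled units.

    ``test_inputs``/``test_targets`` are scaled; residuals are reported
    after inverting the target scaler.
    """
    import pandas as pd

    from .datagen import TARGET_NAMES, invert_scaler
    from .network import forward

    pred = forward(params, np.asarray(test_inputs, float), masks)
    actual = invert_scaler(np.asarray(test_targets, float), scaler)
    predicted = invert_scaler(pred, scaler)
    res = actual - predicted
    return pd.DataFrame({
        "output": list(TARGET_NAMES),
        "mean": res.mean(axis=0),
        "std": res.std(axis=0),
        "min": res.min(axis=0),
        "max": res.max(axis=0),
    })


def rollout_error(params, masks, input_scaler, target_scaler, body_params,
                  cases, duration: float = 0.02, solver_options=None,
                  controls_override=None):
    """Closed-loop evaluation: predict controls, simulate, measure miss.

    ``cases`` is an array of *unscaled* network inputs (n, 10): the initial
    velocities/angles and the requested final pose.  For each case the
    network's predicted (F_x, F_y, tau) are converted to (F, alpha, tau)
    and the stroke is re-simulated from the initial state; the error is the
    Euclidean distance between achieved and requested final
    (x, y, theta, phi).  ``controls_override`` (n, 3) as (F, alpha, tau)
    bypasses the network — used to verify the loop with oracle controls.

    Returns a dict with per-case errors and summary statistics.
    """
    from .datagen import apply_scaler, cartesian_to_controls, invert_scaler
    from .dynamics import simulate_batch_final
    from .network import forward

    cases = np.atleast_2d(np.asarray(cases, dtype=float))
    n = cases.shape[0]
    if n == 0:
        return {"errors": np.array([]), "n": 0, "n_failed": 0,
                "median": np.nan, "mean": np.nan, "max": np.nan}

    if controls_override is not None:
        F, alpha, tau = (np.asarray(controls_override, float)[:, i] for i in range(3))
    else:
        scaled = apply_scaler(cases, input_scaler)
        pred = invert_scaler(forward(params, scaled, masks), target_scaler)
        F, alpha = cartesian_to_controls(pred[:, 0], pred[:, 1])
        tau = pred[:, 2]

    # rebuild initial states: x=y=0; input order (xd, yd, phi, theta, phd, thd, ...)
    states0 = np.zeros((n, 8))
    states0[:, 2] = cases[:, 3]   # theta
    states0[:, 3] = cases[:, 2]   # phi
    states0[:, 4] = cases[:, 0]   # xdot
    states0[:, 5] = cases[:, 1]   # ydot
    states0[:, 6] = cases[:, 5]   # thetadot
    states0[:, 7] = cases[:, 4]   # phidot
    controls = np.column_stack([F, alpha, tau])

    errors = np.full(n, np.nan)
    n_failed = 0
    try:
        finals = simulate_batch_final(states0, controls, body_params, duration,
                                      solver_options)
    except RuntimeError:
        from .dynamics import Controls, State, simulate_segment

        finals = np.full((n, 8), np.nan)
        for i in range(n):
            try:
                traj = simulate_segment(State.from_array(states0[i]),
                                        Controls(*controls[i]), body_params,
                                        duration, solver_options)
                finals[i] = traj.states[-1]
            except (RuntimeError, ValueError):
                n_failed += 1

    # requested final pose: columns (x_f, y_f, phi_f, theta_f) = 6..9
    achieved = finals[:, [0, 1, 3, 2]]          # x, y, phi, theta
    requested = cases[:, 6:10]
    diff = achieved - requested
    errors = np.linalg.norm(diff, axis=1)
    ok = np.isfinite(errors)
    return {
        "errors": errors,
        "per_component": diff,
        "n": n,
        "n_failed": int(n - ok.sum()),
        "median": float(np.nanmedian(errors)) if ok.any() else np.nan,
        "mean": float(np.nanmean(errors)) if ok.any() else np.nan,
        "max": float(np.nanmax(errors)) if ok.any() else np.nan,
    }
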