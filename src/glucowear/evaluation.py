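"""Evaluation: RMSE, Clarke Error Grid Analysis, nested chronological CV,
and the experiment grid runner.

Clarke EGA scores each (reference, predicted) glucose pair into five clinical
zones. Zone A (clinically accurate) admits a relative deviation of at most 20%
of the reference, or pairs where both values lie in the hypoglycemic range
(< 70 mg/dL); zones B-E follow the canonical 1987 piecewise-linear boundaries.

Because sliding windows overlap in time, generalisation is estimated with
chronological blocked cross-validation: outer test folds are contiguous in
time and a purge gap of max(W, H) minutes is removed between train and test so
no training window straddles a test block.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fusion import (
    ParticipantData,
    WindowSpec,
    build_windows,
    window_minmax_apply,
    window_minmax_fit,
)

ZONES = ("A", "B", "C", "D", "E")
HYPO_MG_DL = 70.0


def rmse(observed, predicted) -> float:
    """Root mean squared prediction error, in mg/dL."""
    y = np.asarray(observed, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(y) == 0:
        raise ValueError("rmse of an empty vector is undefined")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def clarke_zones(reference, prediction) -> np.ndarray:
    """Vectorised Clarke zone labels for (reference, prediction) pairs."""
    r = np.asarray(reference, dtype=np.float64)
    p = np.asarray(prediction, dtype=np.float64)
    if np.any(r <= 0) or np.any(p <= 0):
        raise ValueError("glucose values must be positive")
    a = (np.abs(p - r) <= 0.20 * r) | ((r < HYPO_MG_DL) & (p < HYPO_MG_DL))
    e = ((r <= 70) & (p >= 180)) | ((r >= 180) & (p <= 70))
    c = ((70 <= r) & (r <= 290) & (p >= r + 110)) | (
        (130 <= r) & (r <= 180) & (p <= (7.0 / 5.0) * r - 182)
    )
    d = ((r >= 240) & (70 <= p) & (p <= 180)) | ((r < 70) & (70 <= p) & (p <= 180))
    out = np.full(r.shape, "B", dtype="<U1")
    # precedence: A, then E, C, D, else B
    out[d] = "D"
    out[c] = "C"
    out[e] = "E"
    out[a] = "A"
    return out


def clarke_zone(reference: float, prediction: float) -> str:
    """Clarke zone of a single pair."""
    return str(clarke_zones([reference], [prediction])[0])


def ega_summary(reference, prediction) -> pd.DataFrame:
    """Zone counts and percentages over a set of pairs."""
    r = np.asarray(reference, dtype=np.float64)
    if len(r) == 0:
        raise ValueError("ega_summary of an empty set is undefined")
    z = clarke_zones(reference, prediction)
    counts = {zone: int(np.sum(z == zone)) for zone in ZONES}
    total = len(r)
    return pd.DataFrame(
        {
            "zone": ZONES,
            "count": [counts[z] for z in ZONES],
            "percent": [100.0 * counts[z] / total for z in ZONES],
        }
    )


def plot_ega(reference, prediction, path=None, title: str | None = None):
    """Clarke grid scatter (axes 0-400 mg/dL); returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(reference, prediction, s=8, alpha=0.6)
    for lo, hi in [(0, 400)]:
        ax.plot([lo, hi], [lo, hi], "k-", lw=0.8)
        ax.plot([lo, hi], [lo * 1.2, hi * 1.2], "k--", lw=0.6)
        ax.plot([lo, hi], [lo * 0.8, hi * 0.8], "k--", lw=0.6)
    ax.set(xlim=(0, 400), ylim=(0, 400), xlabel="reference (mg/dL)",
           ylabel="prediction (mg/dL)", title=title or "Clarke error grid")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# chronological nested cross-validation


@dataclass
class OuterFold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    inner: list[tuple[np.ndarray, np.ndarray]]


@dataclass
class FoldPlan:
    folds: list[OuterFold]
    purge_gap_s: float


def _purge(train: np.ndarray, t_start, t_target, span_lo, span_hi, gap) -> np.ndarray:
    keep = (t_target[train] < span_lo - gap) | (t_start[train] > span_hi + gap)
    return train[keep]


def make_fold_plan(
    t_start,
    t_target,
    outer_k: int = 5,
    inner_k: int = 3,
    purge_gap_s: float = 0.0,
) -> FoldPlan:
    """Chronological contiguous outer/inner folds with a purge gap.

    Windows must be in chronological order. Training windows whose
    [t_start, t_target] span falls within ``purge_gap_s`` of a test block are
    dropped so overlapping windows never straddle the split.
    """
    t_start = np.asarray(t_start, dtype=np.float64)
    t_target = np.asarray(t_target, dtype=np.float64)
    n = len(t_start)
    if np.any(np.diff(t_start) < 0):
        raise ValueError("windows must be in chronological order")
    if n < 2 * outer_k:
        raise ValueError(f"need at least {2 * outer_k} windows for {outer_k} outer folds")
    folds = []
    for test in np.array_split(np.arange(n), outer_k):
        lo, hi = t_start[test[0]], t_target[test[-1]]
        train = _purge(
            np.setdiff1d(np.arange(n), test), t_start, t_target, lo, hi, purge_gap_s
        )
        inner = []
        for val in np.array_split(train, inner_k):
            if len(val) == 0:
                continue
            vlo, vhi = t_start[val[0]], t_target[val[-1]]
            itr = _purge(
                np.setdiff1d(train, val), t_start, t_target, vlo, vhi, purge_gap_s
            )
            if len(itr):
                inner.append((itr, val))
        folds.append(OuterFold(train, test, inner))
    return FoldPlan(folds, purge_gap_s)


# ---------------------------------------------------------------------------
# experiment runner (observation-window grid x models x channel combinations)

ModelFactory = Callable[[int], object]


def channel_combos(
    optional: Sequence[str] = ("heart_rate", "steps", "activity"),
    always: Sequence[str] = ("glucose",),
) -> list[tuple[str, ...]]:
    """All channel combinations: every subset of ``optional`` joined to ``always``."""
    combos = []
    for mask in range(2 ** len(optional)):
        extra = tuple(c for i, c in enumerate(optional) if mask >> i & 1)
        combos.append(tuple(always) + extra)
    return combos


def _model_seed(base_seed: int, *parts) -> int:
    # stable across processes (unlike built-in str hashing)
    keys = [zlib.crc32(str(p).encode()) for p in parts]
    h = np.random.SeedSequence([base_seed] + keys)
    return int(h.generate_state(1)[0] % 2**31)


def evaluate_cell(
    data: ParticipantData,
    model_factory: ModelFactory,
    spec: WindowSpec,
    seed: int,
    outer_k: int = 5,
    inner_k: int = 3,
) -> dict | None:
    """Nested-CV evaluation of one (model, combo, W, H) cell for one participant.

    Returns fold RMSEs plus pooled test predictions, or None when the cell has
    too few windows for the fold plan.
    """
    ws = build_windows(data.segments, spec, data.cgm)
    if len(ws) < 2 * outer_k:
        return None
    gap = 60.0 * max(spec.observation_minutes, spec.horizon_minutes)
    plan = make_fold_plan(ws.t_start, ws.t_end + spec.horizon_minutes * 60,
                          outer_k, inner_k, gap)
    fold_rmses, refs, preds = [], [], []
    for i, fold in enumerate(plan.folds):
        if len(fold.train_idx) < 2:
            continue
        Xtr, ytr = ws.X[fold.train_idx], ws.y[fold.train_idx]
        Xte, yte = ws.X[fold.test_idx], ws.y[fold.test_idx]
        model = model_factory(_model_seed(seed, i))
        if getattr(model, "requires_scaled_input", False):
            stats = window_minmax_fit(Xtr, ws.channels)
            Xtr = window_minmax_apply(Xtr, stats)
            Xte = window_minmax_apply(Xte, stats)
        model.fit(Xtr, ytr)
        yhat = np.asarray(model.predict(Xte), dtype=np.float64)
        fold_rmses.append(rmse(yte, yhat))
        refs.append(yte)
        preds.append(yhat)
    if not fold_rmses:
        return None
    refs = np.concatenate(refs)
    preds = np.clip(np.concatenate(preds), 1.0, 400.0)  # EGA plotting range
    zones = clarke_zones(np.clip(refs, 1.0, 400.0), preds)
    return {
        "rmse_mean": float(np.mean(fold_rmses)),
        "rmse_folds": [float(v) for v in fold_rmses],
        "n_windows": len(ws),
        "reference": refs,
        "prediction": preds,
        **{f"zone_{z}": int(np.sum(zones == z)) for z in ZONES},
    }


def run_experiment_grid(
    dataset: Mapping[str, ParticipantData],
    models: Mapping[str, ModelFactory],
    W_grid: Sequence[int] = (30, 60, 90),
    H_grid: Sequence[int] = (5, 10, 15, 30, 45, 60),
    combos: Sequence[Sequence[str]] = (("glucose",), ("glucose", "heart_rate", "steps")),
    seed: int = 0,
    stride_seconds: int = 300,
    outer_k: int = 5,
    inner_k: int = 3,
) -> pd.DataFrame:
    """Evaluate every (participant, model, combo, W, H) cell.

    Empty cells (too few windows) are recorded with NaN RMSE, not failure.
    The tidy result frame reproduces the structure of the observation-window,
    model-comparison and channel-ablation experiments.
    """
    if not dataset:
        raise ValueError("dataset must contain at least one participant")
    rows = []
    for pid, data in dataset.items():
        for model_name, factory in models.items():
            for combo in combos:
                for W in W_grid:
                    for H in H_grid:
                        spec = WindowSpec(W, H, stride_seconds, tuple(combo))
                        cell_seed = _model_seed(seed, pid, model_name, *combo, W, H)
                        res = evaluate_cell(data, factory, spec, cell_seed, outer_k, inner_k)
                        row = {
                            "participant": pid,
                            "model": model_name,
                            "combo": "+".join(combo),
                            "W": W,
                            "H": H,
                        }
                        if res is None:
                            row.update(rmse_mean=np.nan, n_windows=0)
                        else:
                            row.update({k: v for k, v in res.items()
                                        if k not in ("reference", "prediction", "rmse_folds")})
                            row["rmse_folds"] = ";".join(f"{v:.4f}" for v in res["rmse_folds"])
                        rows.append(row)
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Best (W, model, combo) per horizon by mean RMSE across participants.

    Ties break to the smaller observation window.
    """
    if report.empty:
        raise ValueError("empty report")
    g = (
        report.dropna(subset=["rmse_mean"])
        .groupby(["model", "combo", "W", "H"], as_index=False)["rmse_mean"]
        .mean()
    )
    if g.empty:
        raise ValueError("report has no evaluated cells")
    g = g.sort_values(["H", "rmse_mean", "W", "model", "combo"], kind="stable")
    return g.groupby("H", as_index=False).first()


# ---------------------------------------------------------------------------
# seeded replicate study (channel ablation and model comparison)


def replicate_ablation_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_participants: int = 2,
    n_days: int = 5,
    num_kernels: int = 250,
    W: int = 60,
    horizons: Sequence[int] = (30, 60),
    stride_seconds: int = 300,
    outer_k: int = 3,
    activity_seeds: int = 10,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Re-run the channel-ablation / model-comparison contrast across seeds.

    For every seed a fresh synthetic cohort is generated (activity logs kept
    at 50% dropout with drink-carb uncertainty on, the regime in which logged
    activities are expected to be uninformative) and Rocket is evaluated with
    glucose alone, glucose+heart_rate+steps, and — on the first
    ``activity_seeds`` seeds — that combination plus the activity channel,
    alongside the persistence baseline. Returns one row per
    (seed, model, combo, H) with the mean test RMSE across participants.

    Scaling choices that keep a single-core run tractable: per-participant
    min-max scaling over all of that participant's windows (the leakage-free
    fold-wise alternative used by ``evaluate_cell`` multiplies the transform
    cost by the fold count), a shared kernel transform between the two
    horizons (the longer horizon's window set is a prefix-subset of the
    shorter's), and common kernel seeds across channel combinations (paired
    comparison).
    """
    from .rocket import apply_kernels, fit_ridge, generate_kernels, _standardize
    from .simulate import SimConfig, simulate_participant
    from .fusion import (
        build_windows,
        prepare_bundle,
        window_minmax_apply,
        window_minmax_fit,
    )

    combos: list[tuple[str, ...]] = [("glucose",), ("glucose", "heart_rate", "steps"),
                                     ("glucose", "heart_rate", "steps", "activity")]
    sim_kwargs = {"activity_dropout_p": 0.5, **(sim_kwargs or {})}

    H_min = min(horizons)
    rows: list[dict] = []
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = SimConfig(n_days=n_days, seed=seed, **sim_kwargs)
        accum: dict[tuple[str, str, int], list[float]] = {}
        for p in range(n_participants):
            data = prepare_bundle(simulate_participant(cfg.for_participant(p)))
            base_ws = {
                H: build_windows(
                    data.segments, WindowSpec(W, H, stride_seconds, tuple(combos[2])),
                    data.cgm,
                )
                for H in horizons
            }
            if any(len(ws) < 2 * outer_k for ws in base_ws.values()):
                continue
            super_ws = base_ws[H_min]
            for combo in combos:
                if combo == combos[2] and s - base_seed >= activity_seeds:
                    continue
                idx = [combos[2].index(c) for c in combo]
                X_raw = super_ws.X[:, idx, :]
                stats = window_minmax_fit(X_raw, combo)
                Xs = window_minmax_apply(X_raw, stats)
                # common kernel seed across combos: paired comparison
                rng = np.random.default_rng(_model_seed(seed, p))
                kernels = generate_kernels(num_kernels, len(combo), W * 60, rng)
                F_all = apply_kernels(Xs, kernels)
                for H in horizons:
                    ws = base_ws[H]
                    keep = np.isin(super_ws.t_end, ws.t_end)
                    F = F_all[keep]
                    plan = make_fold_plan(
                        ws.t_start, ws.t_end + H * 60, outer_k, 3,
                        60.0 * max(W, H),
                    )
                    rk, pr = [], []
                    for fold in plan.folds:
                        res = fit_ridge(F[fold.train_idx], ws.y[fold.train_idx])
                        Z = _standardize(F[fold.test_idx], res.feature_mean, res.feature_scale)
                        rk.append(rmse(ws.y[fold.test_idx], res.intercept + Z @ res.coef))
                        pr.append(rmse(ws.y[fold.test_idx], ws.X[fold.test_idx, 0, -1]))
                    accum.setdefault(("rocket", "+".join(combo), H), []).append(
                        float(np.mean(rk))
                    )
                    if combo == combos[0]:
                        accum.setdefault(("persistence", "glucose", H), []).append(
                            float(np.mean(pr))
                        )
        for (model, combo, H), vals in accum.items():
            rows.append(
                {
                    "seed": seed,
                    "model": model,
                    "combo": combo,
                    "H": H,
                    "rmse": float(np.mean(vals)),
                }
            )
    return pd.DataFrame(rows)
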