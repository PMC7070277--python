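"""Joint-angle prediction model: feature assembly, GRNN fit, evaluation.

The modelling surface follows the statsmodels convention: a model object
(:class:`JointAngleGRNN`) is built from data — a synchronized gait
recording or a pre-assembled feature table — and its :meth:`fit` returns a
results object (:class:`JointAngleResults`) carrying the fitted bandwidth,
held-out predictions, per-joint error metrics and a ``summary()`` table.

The regression task is one-step-ahead: the feature row at time t_k (hip
angle, sEMG RMS features, plantar-pressure features, depending on the
input ablation) predicts the hip/knee/ankle angles at t_{k+1} on the
100 Hz feature clock. Training uses the chronologically first two thirds
of the rows; evaluation the last third. Normalization bounds are computed
on the training rows only and reused (with clipping) for the test rows,
so no test information leaks into the fit.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing as pp
from . import grnn as _grnn
from .config import ABLATIONS, RunConfig
from .metrics import compute_metrics, cycle_extreme_errors
from .synthetic import GaitRecording

__all__ = [
    "FeatureTable",
    "EvaluationReport",
    "JointAngleGRNN",
    "JointAngleResults",
    "build_feature_table",
    "split_train_test",
    "run_pipeline",
]

INPUT_COLUMNS = ("hip_deg", "rms_rf", "rms_bf", "rms_st", "p_toe", "p_fore", "p_heel")
TARGET_COLUMNS = ("hip_deg", "knee_deg", "ankle_deg")
JOINTS = ("hip", "knee", "ankle")

ABLATION_INPUTS = {
    "angle_only": INPUT_COLUMNS[:1],
    "angle_semg": INPUT_COLUMNS[:4],
    "angle_semg_pressure": INPUT_COLUMNS,
}

# Row labels of the per-joint error-analysis table.
REPORT_ROWS = (
    "Mean Maximum Positive Error",
    "Mean Maximum Negative Error",
    "RMSE",
    "MRE",
    "gamma",
)


class AlignmentError(ValueError):
    """Raised when processed channels cannot be aligned to one clock."""


@dataclass
class FeatureTable:
    """Time-aligned feature rows and one-step-ahead targets.

    ``inputs.iloc[k]`` is observed at ``t[k]``; ``targets.iloc[k]`` holds
    the measured angles at ``t[k] + 1/feature_rate`` (the next feature
    step). The last measured sample therefore produces no row.
    """

    t: np.ndarray
    inputs: pd.DataFrame
    targets: pd.DataFrame
    cycle_id: np.ndarray
    ablation: str

    def __len__(self) -> int:
        return len(self.inputs)

    def validate(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        expected = list(ABLATION_INPUTS[self.ablation])
        if list(self.inputs.columns) != expected:
            raise ValueError(
                f"input columns {list(self.inputs.columns)} != expected {expected}"
            )
        if list(self.targets.columns) != list(TARGET_COLUMNS):
            raise ValueError(f"target columns must be {TARGET_COLUMNS}")
        if not (len(self.inputs) == len(self.targets) == self.t.size == self.cycle_id.size):
            raise ValueError("inputs, targets, t and cycle_id must have equal length")


def _denoise(x: np.ndarray, config: RunConfig) -> np.ndarray:
    if config.denoise_method == "threshold":
        return pp.wavelet_denoise(
            x, config.wavelet, config.wavelet_levels, config.threshold_mode
        )
    if config.denoise_method == "lowpass":
        return pp.wavelet_lowpass(x, config.wavelet, config.wavelet_levels)
    return np.asarray(x, dtype=float)


def build_feature_table(
    recording: GaitRecording,
    ablation: str = "angle_semg_pressure",
    config: RunConfig | None = None,
) -> FeatureTable:
    """Run per-channel preprocessing and assemble the regression dataset.

    sEMG channels are band-pass filtered and reduced to windowed RMS;
    pressure channels are reduced to windowed means and wavelet-denoised;
    angle channels are spline-fitted and resampled onto the feature clock.
    The ablation selects 1 (angle-only), 4 (+sEMG) or 7 (+pressure) input
    columns; the targets are always the three next-step joint angles.
    """
    if ablation not in ABLATIONS:
        raise ValueError(f"ablation must be one of {ABLATIONS}, got {ablation!r}")
    config = config or RunConfig()
    recording.validate()

    filt = pp.design_bandpass(config.bandpass_spec())
    channels: dict[str, np.ndarray] = {}
    for ch in ("rf", "bf", "st"):
        filtered = pp.apply_filter(filt, recording.semg[ch])
        channels[f"rms_{ch}"] = pp.windowed_rms(filtered, config.window)
    for ch in ("toe", "fore", "heel"):
        feat = pp.windowed_mean(recording.pressure[ch], config.window)
        channels[f"p_{ch}"] = _denoise(feat, config)
    for ch in ("hip", "knee", "ankle"):
        series = pp.resample_angles(
            recording.time_angle,
            recording.angles[ch],
            out_rate=config.feature_rate,
            fit_window=config.fit_window,
            channel_name=f"{ch}_deg",
        )
        channels[f"{ch}_deg"] = series.values

    lengths = {ch: x.size for ch, x in channels.items()}
    n = min(lengths.values())
    if max(lengths.values()) - n > 1:
        raise AlignmentError(f"post-processing channel lengths diverge: {lengths}")
    channels = {ch: x[:n] for ch, x in channels.items()}
    t = np.arange(n) / config.feature_rate + recording.time_semg[0]

    cycles_semg = recording.cycle_index()
    cycle_id = cycles_semg[:: config.window][:n]

    inputs = pd.DataFrame(
        {c: channels[c] for c in ABLATION_INPUTS[ablation]}
    ).iloc[:-1].reset_index(drop=True)
    targets = pd.DataFrame(
        {c: channels[c] for c in TARGET_COLUMNS}
    ).iloc[1:].reset_index(drop=True)

    table = FeatureTable(
        t=t[:-1], inputs=inputs, targets=targets, cycle_id=cycle_id[:-1], ablation=ablation
    )
    table.validate()
    return table


def split_train_test(
    table: FeatureTable, train_fraction: float = 2.0 / 3.0
) -> tuple[FeatureTable, FeatureTable]:
    """Chronological split at floor(N * train_fraction) rows (no shuffling)."""
    n = len(table)
    if n < 3:
        raise ValueError(f"need at least 3 rows to split, got {n}")
    k = int(np.floor(n * train_fraction))
    if k < 1 or k >= n:
        raise ValueError(f"train_fraction {train_fraction} leaves an empty split")

    def _slice(lo, hi):
        return FeatureTable(
            t=table.t[lo:hi],
            inputs=table.inputs.iloc[lo:hi].reset_index(drop=True),
            targets=table.targets.iloc[lo:hi].reset_index(drop=True),
            cycle_id=table.cycle_id[lo:hi],
            ablation=table.ablation,
        )

    return _slice(0, k), _slice(k, n)


@dataclass
class EvaluationReport:
    """Per-joint error analysis for one input-ablation configuration."""

    ablation: str
    sigma: float | None
    sigma_mode: str
    n_train: int
    n_test: int
    joints: dict[str, dict[str, float]]
    config_hash: str = ""
    elapsed_s: float | None = None

    def to_dict(self, include_timing: bool = False) -> dict:
        doc = {
            "ablation": self.ablation,
            "sigma": self.sigma,
            "sigma_mode": self.sigma_mode,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "config_hash": self.config_hash,
            "joints": self.joints,
        }
        if include_timing and self.elapsed_s is not None:
            doc["elapsed_s"] = self.elapsed_s
        return doc

    def to_json(self, include_timing: bool = False) -> str:
        import json

        return json.dumps(self.to_dict(include_timing=include_timing), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationReport":
        return cls(
            ablation=doc["ablation"],
            sigma=doc["sigma"],
            sigma_mode=doc["sigma_mode"],
            n_train=doc["n_train"],
            n_test=doc["n_test"],
            joints=doc["joints"],
            config_hash=doc.get("config_hash", ""),
            elapsed_s=doc.get("elapsed_s"),
        )

    def summary(self) -> str:
        """Plain-text error-analysis table (rows: metric, columns: joint)."""
        keys = {
            "Mean Maximum Positive Error": "mean_max_pos_err",
            "Mean Maximum Negative Error": "mean_max_neg_err",
            "RMSE": "rmse",
            "MRE": "mre",
            "gamma": "gamma",
        }
        sigma_txt = "n/a" if self.sigma is None else f"{self.sigma:.6g}"
        lines = [
            f"Joint-angle prediction error analysis  [inputs: {self.ablation}]",
            f"sigma = {sigma_txt} ({self.sigma_mode}); "
            f"n_train = {self.n_train}, n_test = {self.n_test}",
            "",
            f"{'Index':<32}{'Hip':>12}{'Knee':>12}{'Ankle':>12}",
        ]
        for label in REPORT_ROWS:
            key = keys[label]
            vals = [self.joints[j][key] for j in JOINTS]
            lines.append(f"{label:<32}" + "".join(f"{v:>12.4f}" for v in vals))
        return "\n".join(lines)


class JointAngleGRNN:
    """GRNN model of next-step lower-limb joint angles.

    Parameters
    ----------
    table : FeatureTable
        Aligned inputs and one-step-ahead targets on the feature clock.
    config : RunConfig, optional
        Pipeline tunables; defaults to the standard protocol.
    """

    def __init__(self, table: FeatureTable, config: RunConfig | None = None):
        table.validate()
        self.table = table
        self.config = (config or RunConfig()).with_overrides(ablation=table.ablation)

    @classmethod
    def from_recording(
        cls,
        recording: GaitRecording,
        ablation: str = "angle_semg_pressure",
        config: RunConfig | None = None,
    ) -> "JointAngleGRNN":
        table = build_feature_table(recording, ablation=ablation, config=config)
        return cls(table, config=config)

    def fit(self, sigma: float | str = "optimize") -> "JointAngleResults":
        """Train on the first two thirds, predict and score the last third.

        ``sigma`` is either a positive float (fixed bandwidth) or
        ``"optimize"`` to run the golden-section leave-one-out search.
        """
        t0 = time.perf_counter()
        cfg = self.config
        train, test = split_train_test(self.table, cfg.train_fraction)

        norm_bounds: dict[str, tuple[float, float]] = {}
        for col in train.inputs.columns:
            _, norm_bounds[col] = pp.minmax_normalize(train.inputs[col].to_numpy())
        for col in train.targets.columns:
            key = f"target_{col}"
            _, norm_bounds[key] = pp.minmax_normalize(train.targets[col].to_numpy())
        norm = pp.NormalizationParams(norm_bounds)

        def _norm_inputs(tbl: FeatureTable) -> np.ndarray:
            cols = [
                pp.minmax_normalize(tbl.inputs[c].to_numpy(), norm[c])[0]
                for c in tbl.inputs.columns
            ]
            return np.column_stack(cols)

        def _norm_targets(tbl: FeatureTable) -> np.ndarray:
            cols = [
                pp.minmax_normalize(tbl.targets[c].to_numpy(), norm[f"target_{c}"])[0]
                for c in tbl.targets.columns
            ]
            return np.column_stack(cols)

        X_train, Y_train = _norm_inputs(train), _norm_targets(train)

        if isinstance(sigma, str):
            if sigma != "optimize":
                raise ValueError(f"sigma must be a float or 'optimize', got {sigma!r}")
            grnn = _grnn.optimize_sigma(X_train, Y_train, cfg.gs_config(), norm_params=norm)
            sigma_mode = "optimize"
        else:
            grnn = _grnn.fit(X_train, Y_train, float(sigma), norm_params=norm)
            sigma_mode = "fixed"

        pred_deg, pred_norm = predict_table(grnn, test, cfg)

        joints: dict[str, dict[str, float]] = {}
        for joint, col in zip(JOINTS, TARGET_COLUMNS):
            actual = test.targets[col].to_numpy()
            pred = pred_deg[col]
            m = compute_metrics(pred, actual, cfg.mre_floor_frac)
            pos, neg = cycle_extreme_errors(pred, actual, test.cycle_id)
            joints[joint] = {
                "mean_max_pos_err": pos,
                "mean_max_neg_err": neg,
                "rmse": m.rmse,
                "mre": m.mre,
                "gamma": m.gamma,
                "mre_excluded": m.mre_excluded,
            }

        report = EvaluationReport(
            ablation=self.table.ablation,
            sigma=grnn.sigma,
            sigma_mode=sigma_mode,
            n_train=len(train),
            n_test=len(test),
            joints=joints,
            config_hash=cfg.hash(),
            elapsed_s=time.perf_counter() - t0,
        )

        predictions = predictions_frame(test.t, pred_deg, test.targets)

        return JointAngleResults(
            model=self,
            grnn=grnn,
            train=train,
            test=test,
            predictions=predictions,
            predictions_normalized=pred_norm,
            report=report,
        )

    def fit_baseline(self, estimator) -> "JointAngleResults":
        """Experimental: fit any sklearn-style multi-output regressor
        (``fit``/``predict``) on the same normalized one-step task.

        The surrounding pipeline — normalization from training rows,
        wavelet denoising of the predicted series, denormalization and
        the per-joint error analysis — is identical to the GRNN path, so
        reports are directly comparable. Baseline numbers are
        informational; they are not part of the package's contracts.
        """
        t0 = time.perf_counter()
        cfg = self.config
        train, test = split_train_test(self.table, cfg.train_fraction)

        norm_bounds: dict[str, tuple[float, float]] = {}
        for col in train.inputs.columns:
            _, norm_bounds[col] = pp.minmax_normalize(train.inputs[col].to_numpy())
        for col in train.targets.columns:
            _, norm_bounds[f"target_{col}"] = pp.minmax_normalize(
                train.targets[col].to_numpy()
            )
        norm = pp.NormalizationParams(norm_bounds)

        X_train = np.column_stack(
            [
                pp.minmax_normalize(train.inputs[c].to_numpy(), norm[c])[0]
                for c in train.inputs.columns
            ]
        )
        Y_train = np.column_stack(
            [
                pp.minmax_normalize(train.targets[c].to_numpy(), norm[f"target_{c}"])[0]
                for c in train.targets.columns
            ]
        )
        X_test = np.column_stack(
            [
                pp.minmax_normalize(test.inputs[c].to_numpy(), norm[c])[0]
                for c in test.inputs.columns
            ]
        )
        estimator.fit(X_train, Y_train)
        pred_norm = np.atleast_2d(np.asarray(estimator.predict(X_test), dtype=float))
        if pred_norm.shape != (len(test), len(TARGET_COLUMNS)):
            raise ValueError(
                f"baseline estimator returned shape {pred_norm.shape}, "
                f"expected {(len(test), len(TARGET_COLUMNS))}"
            )
        pred_deg = {}
        for j, col in enumerate(TARGET_COLUMNS):
            series = _denoise(pred_norm[:, j], cfg)
            pred_deg[col] = pp.minmax_denormalize(series, norm[f"target_{col}"])

        joints: dict[str, dict[str, float]] = {}
        for joint, col in zip(JOINTS, TARGET_COLUMNS):
            actual = test.targets[col].to_numpy()
            m = compute_metrics(pred_deg[col], actual, cfg.mre_floor_frac)
            pos, neg = cycle_extreme_errors(pred_deg[col], actual, test.cycle_id)
            joints[joint] = {
                "mean_max_pos_err": pos,
                "mean_max_neg_err": neg,
                "rmse": m.rmse,
                "mre": m.mre,
                "gamma": m.gamma,
                "mre_excluded": m.mre_excluded,
            }
        report = EvaluationReport(
            ablation=self.table.ablation,
            sigma=None,
            sigma_mode=f"baseline:{type(estimator).__name__}",
            n_train=len(train),
            n_test=len(test),
            joints=joints,
            config_hash=cfg.hash(),
            elapsed_s=time.perf_counter() - t0,
        )
        return JointAngleResults(
            model=self,
            grnn=None,
            train=train,
            test=test,
            predictions=predictions_frame(test.t, pred_deg, test.targets),
            predictions_normalized=pred_norm,
            report=report,
        )


@dataclass
class JointAngleResults:
    """Fit results: the trained network, held-out predictions and scores."""

    model: JointAngleGRNN
    grnn: _grnn.GRNN | None
    train: FeatureTable
    test: FeatureTable
    predictions: pd.DataFrame
    predictions_normalized: np.ndarray
    report: EvaluationReport

    @property
    def sigma(self) -> float | None:
        return None if self.grnn is None else self.grnn.sigma

    @property
    def trace(self) -> list[tuple[float, float]] | None:
        """Golden-section (sigma, objective) evaluations, if optimized."""
        return None if self.grnn is None else self.grnn.trace_

    def summary(self) -> str:
        return self.report.summary()

    def plot(self, ax=None):
        """Predicted vs measured angle series for the held-out span."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
        else:
            axes = ax
        for a, col in zip(np.atleast_1d(axes), TARGET_COLUMNS):
            a.plot(self.predictions["t_s"], self.predictions[f"actual_{col}"], label="measured")
            a.plot(self.predictions["t_s"], self.predictions[f"pred_{col}"], "--", label="predicted")
            a.set_ylabel(f"{col.replace('_deg', '')} (deg)")
        np.atleast_1d(axes)[0].legend(loc="upper right")
        np.atleast_1d(axes)[-1].set_xlabel("time (s)")
        return axes


def predict_table(
    grnn: _grnn.GRNN, table: FeatureTable, config: RunConfig
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Apply a fitted GRNN to a feature table's input rows.

    Normalizes the inputs with the bounds stored on the model (clipping
    out-of-range values), predicts, denoises each predicted angle series
    and denormalizes back to degrees. Returns the per-channel degree
    predictions and the raw normalized network outputs. A saved and
    reloaded model reproduces these predictions bit-exactly.
    """
    norm = grnn.norm_params
    if norm is None:
        raise ValueError("model carries no normalization bounds")
    cols = [
        pp.minmax_normalize(table.inputs[c].to_numpy(), norm[c])[0]
        for c in table.inputs.columns
    ]
    pred_norm = grnn.predict(np.column_stack(cols))
    pred_deg = {}
    for j, col in enumerate(TARGET_COLUMNS):
        series = _denoise(pred_norm[:, j], config)
        pred_deg[col] = pp.minmax_denormalize(series, norm[f"target_{col}"])
    return pred_deg, pred_norm


def predictions_frame(t: np.ndarray, pred_deg: dict, targets: pd.DataFrame) -> pd.DataFrame:
    predictions = pd.DataFrame({"t_s": t})
    for col in TARGET_COLUMNS:
        predictions[f"pred_{col}"] = pred_deg[col]
        predictions[f"actual_{col}"] = targets[col].to_numpy()
    return predictions


def run_pipeline(
    recording: GaitRecording,
    ablation: str = "angle_semg_pressure",
    sigma: float | str = "optimize",
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Convenience wrapper: recording -> features -> fit -> evaluation."""
    model = JointAngleGRNN.from_recording(recording, ablation=ablation, config=config)
    res = model.fit(sigma=sigma)
    return res.predictions, res.report
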