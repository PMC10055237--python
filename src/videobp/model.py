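"""Model / Results front end for blood-pressure estimation.

`BloodPressureModel` is built from per-subject records (labels + RGB
spatiotemporal maps) for one target (SBP or DBP); ``fit()`` runs the full
training protocol — grouping, subject-level split, balanced oversampling,
ADAM — and returns a :class:`BloodPressureResults` carrying the best weight
snapshot, the training history, validation predictions and the standard
error metrics, with a ``summary()`` table in the style of statistical
modelling packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bpe_net import GroupScheme, ModelConfig
from .evaluation import MetricsReport, compute_metrics
from .synthetic_data import SynthConfig, generate_dataset, make_records
from .training import BPRecord, TrainConfig, predict as _predict, train as _train


class BloodPressureModel:
    """Joint interval-classification / value-regression BP estimator.

    Parameters
    ----------
    records : list of BPRecord
        One record per subject with labels and the RGB spatiotemporal map.
    target : {"sbp", "dbp"}
        Which pressure to estimate; SBP and DBP use separate models and
        separate grouping schemes.
    scheme : GroupScheme, optional
        Interval binning; defaults to the standard 4-group scheme for the
        target.
    model_config : ModelConfig, optional
        Network architecture and fusion weights.
    """

    def __init__(
        self,
        records: list[BPRecord],
        target: str = "sbp",
        scheme: GroupScheme | None = None,
        model_config: ModelConfig | None = None,
    ):
        if target not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")
        if not records:
            raise ValueError("need at least one record")
        self.records = list(records)
        self.target = target
        self.scheme = scheme or GroupScheme.default_for(target)
        self.model_config = model_config or ModelConfig()

    @classmethod
    def from_dataframe(cls, labels: pd.DataFrame, maps: dict, target: str = "sbp", **kwargs) -> "BloodPressureModel":
        """Build from a labels table (subject_id, sbp, dbp) plus a dict
        ``subject_id -> SpatioTemporalMap``."""
        records = []
        for _, row in labels.iterrows():
            sid = str(row["subject_id"])
            if sid not in maps:
                raise KeyError(f"no spatiotemporal map for subject {sid}")
            records.append(BPRecord(subject_id=sid, sbp=float(row["sbp"]), dbp=float(row["dbp"]), stmap=maps[sid]))
        return cls(records, target=target, **kwargs)

    @classmethod
    def from_synthetic(cls, config: SynthConfig, target: str = "sbp", **kwargs) -> "BloodPressureModel":
        """Generate a synthetic cohort (fast mode) and build the model on it."""
        return cls(make_records(generate_dataset(config)), target=target, **kwargs)

    def fit(self, train_config: TrainConfig | None = None) -> "BloodPressureResults":
        """Run the training protocol; returns the results object."""
        cfg = train_config or TrainConfig()
        snapshot, history = _train(self.records, self.model_config, cfg, self.scheme)
        return BloodPressureResults(self, snapshot, history)


class BloodPressureResults:
    """Fit artifacts: snapshot, history, validation diagnostics.

    Attributes
    ----------
    snapshot : dict
        Best-validation weights plus configs (reloadable by ``predict``).
    history : DataFrame
        Per-epoch train loss and validation MAE.
    val_predictions : DataFrame
        Held-out per-subject predictions (fused, calculator, interval).
    metrics : MetricsReport
        SD / RMSE / MAE and threshold proportions on the validation split.
    """

    def __init__(self, model: BloodPressureModel, snapshot: dict, history: pd.DataFrame):
        self.model = model
        self.snapshot = snapshot
        self.history = history
        val_ids = set(snapshot["val_subjects"])
        self._val_records = [r for r in model.records if r.subject_id in val_ids]
        self._train_records = [r for r in model.records if r.subject_id in set(snapshot["train_subjects"])]
        self.val_predictions = _predict(self._val_records, snapshot) if self._val_records else pd.DataFrame()
        self.metrics = self._compute_metrics()

    # -- diagnostics --------------------------------------------------------
    def _compute_metrics(self) -> MetricsReport | None:
        if self.val_predictions.empty:
            return None
        return compute_metrics(
            self.val_predictions["r_final"],
            self.val_predictions["truth"],
            target=self.model.target,
            groups=self.val_predictions["group"],
        )

    @property
    def val_mae(self) -> float:
        return float(self.snapshot["val_mae"])

    @property
    def baseline_mae(self) -> float:
        """Validation MAE of always predicting the training-label mean."""
        y_train = np.array([r.bp(self.model.target) for r in self._train_records])
        y_val = np.array([r.bp(self.model.target) for r in self._val_records])
        return float(np.abs(y_val - y_train.mean()).mean())

    @property
    def classifier_accuracy(self) -> float:
        """4-way interval accuracy on the validation split."""
        df = self.val_predictions
        return float((df["r_cla_argmax"] == df["group"]).mean())

    def predict(self, records: list[BPRecord]) -> pd.DataFrame:
        """Apply the fitted snapshot to new records."""
        return _predict(records, self.snapshot)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        m = self.metrics
        sch = self.model.scheme
        lines = [
            "Blood Pressure Estimation Results",
            "=" * 56,
            f"Target:                {self.model.target.upper()}",
            f"Subjects (train/val):  {len(self._train_records)} / {len(self._val_records)}",
            f"Group edges (mmHg):    {tuple(sch.bin_edges)}",
            f"Reference values STA:  {tuple(sch.sta)}",
            f"Epochs run / best:     {len(self.history)} / {self.snapshot['best_epoch']}",
            "-" * 56,
            f"Validation MAE:        {self.val_mae:8.2f} mmHg",
            f"Baseline (mean) MAE:   {self.baseline_mae:8.2f} mmHg",
        ]
        if m is not None:
            lines += [
                f"Validation RMSE:       {m.rmse:8.2f} mmHg",
                f"Validation SD:         {m.sd:8.2f} mmHg",
                f"Classifier accuracy:   {self.classifier_accuracy:8.2f}",
            ]
            for thr, frac in sorted(m.pct_within.items()):
                lines.append(f"|error| < {thr:g} mmHg:".ljust(23) + f"{100 * frac:7.1f} %")
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_history(self, path=None):
        """Loss / validation-MAE curves; saves to ``path`` or returns the figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(self.history["epoch"], self.history["train_loss"])
        axes[0].set_xlabel("epoch")
        axes[0].set_ylabel("train loss")
        axes[1].plot(self.history["epoch"], self.history["val_mae"])
        axes[1].axhline(self.baseline_mae, color="grey", ls="--", label="mean baseline")
        axes[1].set_xlabel("epoch")
        axes[1].set_ylabel("validation MAE (mmHg)")
        axes[1].legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig
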