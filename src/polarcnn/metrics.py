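"""Classification metrics, multi-run aggregates, net benefit and kappa.

All metrics are derived from the 2x2 confusion table with ischemic = 1 as
the positive class:

    SEN = TP/(TP+FN)        SPE = TN/(TN+FP)       PRE = TP/(TP+FP)
    ACC = (TP+TN)/N         F1S = 2*PRE*SEN/(PRE+SEN)

The classifier emits hard binary labels, so the ROC has a single interior
operating point and AUC reduces to the two-segment trapezoid
(SEN + SPE)/2. Metrics with a zero denominator are reported as NaN
(undefined) rather than silently as 0.

Decision-curve net benefit (Vickers & Elkin):
    NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t),  p_t in [0, 1).
Negative values are retained; clipping happens only in the plot.

Cohen's kappa uses the marginal-product expected agreement:
    kappa = (p_o - p_e) / (1 - p_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNDEFINED = float("nan")

METRIC_NAMES = ("ACC", "AUC", "F1S", "SEN", "SPE", "PRE")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    ACC: float
    AUC: float
    F1S: float
    SEN: float
    SPE: float
    PRE: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    context: str = ""


def confusion(predicted, reference) -> ConfusionCounts:
    """2x2 confusion counts; positive class = ischemic = 1."""
    pred = np.asarray(predicted, dtype=int)
    ref = np.asarray(reference, dtype=int)
    if pred.shape != ref.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {ref.shape} references"
        )
    if not (np.isin(pred, (0, 1)).all() and np.isin(ref, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(((pred == 1) & (ref == 1)).sum()),
        TN=int(((pred == 0) & (ref == 0)).sum()),
        FP=int(((pred == 1) & (ref == 0)).sum()),
        FN=int(((pred == 0) & (ref == 1)).sum()),
    )


def _ratio(num, den) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    sen = _ratio(c.TP, c.TP + c.FN)
    spe = _ratio(c.TN, c.TN + c.FP)
    pre = _ratio(c.TP, c.TP + c.FP)
    acc = _ratio(c.TP + c.TN, c.total)
    f1 = (
        2.0 * pre * sen / (pre + sen)
        if np.isfinite(pre) and np.isfinite(sen) and (pre + sen) > 0
        else UNDEFINED
    )
    auc = (sen + spe) / 2.0  # two-point ROC for hard binary predictions
    return MetricSet(ACC=acc, AUC=auc, F1S=f1, SEN=sen, SPE=spe, PRE=pre)


def metrics_from_labels(predicted, reference) -> MetricSet:
    return compute_metrics(confusion(predicted, reference))


def aggregate_runs(metric_sets) -> pd.DataFrame:
    """Median and interquartile range per metric over runs.

    Quartiles use linear interpolation (numpy's default, 'type 7'); the
    result is independent of run order.
    """
    metric_sets = list(metric_sets)
    if not metric_sets:
        raise ValueError("need at least one run")
    rows = []
    for name in METRIC_NAMES:
        vals = np.array([m.as_dict()[name] for m in metric_sets], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"metric": name, "median": med, "iqr": q3 - q1})
    return pd.DataFrame(rows).set_index("metric")


def decision_curve(c: ConfusionCounts, N: int | None = None, grid=None) -> pd.DataFrame:
    """Net benefit over a grid of threshold probabilities in [0, 1)."""
    N = c.total if N is None else N
    grid = np.linspace(0.0, 0.99, 100) if grid is None else np.asarray(grid, float)
    if (grid < 0).any() or (grid >= 1).any():
        raise ValueError("threshold probabilities must lie in [0, 1)")
    nb = c.TP / N - (c.FP / N) * grid / (1.0 - grid)
    return pd.DataFrame({"p_t": grid, "net_benefit": nb})


def net_benefit(c: ConfusionCounts, p_t: float, N: int | None = None) -> float:
    """Net benefit at a single threshold probability."""
    N = c.total if N is None else N
    if not 0.0 <= p_t < 1.0:
        raise ValueError("p_t must lie in [0, 1)")
    return c.TP / N - (c.FP / N) * p_t / (1.0 - p_t)


def plot_decision_curve(curves: dict, path=None):
    """Plot one or more labelled decision curves (positive values only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in curves.items():
        pos = df["net_benefit"] >= 0
        ax.plot(df.loc[pos, "p_t"], df.loc[pos, "net_benefit"], label=label)
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=0)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def cohen_kappa(indicator_a, indicator_b, context: str = "") -> AgreementResult:
    """Chance-corrected agreement between two binary per-subject ratings."""
    a = np.asarray(indicator_a, dtype=int)
    b = np.asarray(indicator_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("indicator vectors must have equal length")
    n = a.size
    p_o = float((a == b).mean())
    p_a1, p_b1 = a.mean(), b.mean()
    p_e = float(p_a1 * p_b1 + (1.0 - p_a1) * (1.0 - p_b1))
    if np.isclose(p_e, 1.0):
        return AgreementResult(
            UNDEFINED, p_o, p_e, context or "both raters constant; kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(float(kappa), p_o, p_e, context)
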