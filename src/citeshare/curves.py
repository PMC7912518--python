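"""Aggregation of per-article records into curves, coverage and extrapolations.

Per-article overlap records are stratified by annotated-neighbor count into
curve points (mean recall, mean precision, MAP per bin), summarized into
corpus-wide statistics, and — for extrapolating what recall a better-connected
corpus would reach — fitted with a bounded-growth sigmoid

    recall(x) = L / (1 + exp(-k · (x - x0)))

where ``x`` is the annotated-neighbor count, ``L`` the recall ceiling in
[0, 1], ``k`` the growth steepness and ``x0`` the midpoint. The sigmoid is
used because it is monotone and bounded, matching how per-article recall
saturates as neighborhoods grow.

The fit is exposed statsmodels-style: ``SigmoidRecallModel(x, y).fit()``
returns a :class:`SigmoidRecallResults` carrying estimates, bootstrap
confidence intervals, R² and ``predict``/``summary`` methods.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .ingest import AnnotationStore, ArticleID
from .metrics import OverlapRecord
from .network import CitationGraph, neighborhood_profile


class DegenerateFitError(ValueError):
    """Raised when the response is constant (SS_tot = 0) or the fit diverges."""


def sigmoid(x: np.ndarray | float, L: float, k: float, x0: float) -> np.ndarray | float:
    return L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0)))


@dataclass
class CurvePoint:
    """Mean overlap statistics for records sharing one annotated-neighbor count.

    ``open_ended`` marks the terminal pooled bin holding every record above
    the cut-off; it is reported but conventionally excluded from curve plots.
    """

    bin: int
    n_records: int
    mean_recall: float
    mean_precision: float
    map: float
    open_ended: bool = False

    TSV_HEADER = "bin\tn_records\tmean_recall\tmean_precision\tmap\topen_ended"

    def to_tsv_row(self) -> str:
        return (f"{self.bin}\t{self.n_records}\t{self.mean_recall:.10g}\t"
                f"{self.mean_precision:.10g}\t{self.map:.10g}\t{int(self.open_ended)}")


def stratify(
    records: Sequence[OverlapRecord],
    max_bin: int = 20,
    include_pooled: bool = True,
) -> list[CurvePoint]:
    """One curve point per exact annotated-neighbor count 1..``max_bin``.

    Records above the cut-off pool into a terminal open-ended bin (labelled
    ``max_bin + 1``). Bins with no records are omitted; an empty input yields
    an empty curve.
    """
    points: list[CurvePoint] = []
    by_bin: dict[int, list[OverlapRecord]] = {}
    pooled: list[OverlapRecord] = []
    for rec in records:
        if rec.n_annotated_neighbors <= max_bin:
            by_bin.setdefault(rec.n_annotated_neighbors, []).append(rec)
        else:
            pooled.append(rec)
    for b in sorted(by_bin):
        rs = by_bin[b]
        points.append(CurvePoint(
            bin=b,
            n_records=len(rs),
            mean_recall=float(np.mean([r.recall for r in rs])),
            mean_precision=float(np.mean([r.precision for r in rs])),
            map=float(np.mean([r.ap for r in rs])),
        ))
    if pooled and include_pooled:
        points.append(CurvePoint(
            bin=max_bin + 1,
            n_records=len(pooled),
            mean_recall=float(np.mean([r.recall for r in pooled])),
            mean_precision=float(np.mean([r.precision for r in pooled])),
            map=float(np.mean([r.ap for r in pooled])),
            open_ended=True,
        ))
    return points


def write_curve(points: Sequence[CurvePoint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(CurvePoint.TSV_HEADER + "\n")
        for p in points:
            fh.write(p.to_tsv_row() + "\n")


def corpus_recall(records: Sequence[OverlapRecord]) -> float:
    """Annotation-weighted corpus recall.

    Total annotations recovered across all target articles divided by total
    annotations — NOT the mean of per-article recalls; articles with many
    annotations weigh more.
    """
    total = sum(r.n_article_annots for r in records)
    if total == 0:
        raise ValueError("corpus_recall undefined: zero total annotations")
    return sum(r.n_shared for r in records) / total


def fraction_full_recall(records: Sequence[OverlapRecord]) -> float:
    """Share of records whose annotations were all recovered (recall = 1).

    Full recall is decided by the exact integer identity
    ``n_shared == n_article_annots`` — recall is a ratio of small integers, so
    no float tolerance is involved. The denominator is the evaluated records
    (articles excluded for lack of annotated neighbors are not in it); callers
    wanting a whole-corpus denominator divide by their own target count.
    """
    if not records:
        return 0.0
    full = sum(1 for r in records if r.n_shared == r.n_article_annots)
    return full / len(records)


def coverage(
    graph: CitationGraph,
    store: AnnotationStore,
    universe: Iterable[ArticleID],
    min_annotated_neighbors: int = 1,
    degree: int = 1,
    mode: str = "undirected",
) -> float:
    """Fraction of a corpus with at least ``min_annotated_neighbors`` annotated neighbors.

    Measures how much of a literature the neighborhood method can reach at
    all: articles below the threshold cannot be scored.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("coverage undefined over an empty universe")
    n_ok = 0
    for article in universe:
        profile = neighborhood_profile(graph, store, article, mode=mode, degree=degree)
        if profile.annotated_neighbors >= min_annotated_neighbors:
            n_ok += 1
    return n_ok / len(universe)


# ---------------------------------------------------------------------------
# Sigmoid recall extrapolation
# ---------------------------------------------------------------------------

@dataclass
class SigmoidRecallResults:
    """Fitted sigmoid parameters with bootstrap uncertainty.

    ``params`` is (L, k, x0); ``param_ci`` maps each name to its bootstrap
    percentile interval. ``boot_params`` holds the bootstrap replicate
    estimates so prediction bands can be recomputed at any x.
    """

    L: float
    k: float
    x0: float
    r_squared: float
    residual_sd: float
    n_obs: int
    ci_level: float = 0.95
    seed: int | None = None
    param_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    boot_params: np.ndarray | None = None  # shape (n_boot, 3)

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.L, self.k, self.x0)

    def predict(self, x, ci: bool = False):
        """Predicted recall at annotated-neighbor count ``x``, clipped to [0, 1].

        With ``ci=True`` returns (estimate, lower, upper) using bootstrap
        percentile bands of the fitted curve at each x.
        """
        y = np.clip(sigmoid(x, self.L, self.k, self.x0), 0.0, 1.0)
        if not ci:
            return y
        if self.boot_params is None or not len(self.boot_params):
            raise ValueError("no bootstrap replicates available for CI bands")
        curves = np.clip(
            np.stack([sigmoid(x, *p) for p in self.boot_params]), 0.0, 1.0
        )
        alpha = (1.0 - self.ci_level) / 2.0
        lo = np.quantile(curves, alpha, axis=0)
        hi = np.quantile(curves, 1.0 - alpha, axis=0)
        return y, lo, hi

    def summary(self) -> str:
        lines = [
            "Sigmoid recall fit: recall(x) = L / (1 + exp(-k (x - x0)))",
            f"  n_obs      {self.n_obs}",
            f"  R-squared  {self.r_squared:.4f}",
            f"  residual sd {self.residual_sd:.4f}",
            "  param   estimate   " +
            (f"{int(self.ci_level*100)}% CI" if self.param_ci else ""),
        ]
        for name, value in zip(("L", "k", "x0"), self.params):
            ci = self.param_ci.get(name)
            tail = f"   [{ci[0]:.4f}, {ci[1]:.4f}]" if ci else ""
            lines.append(f"  {name:<6} {value:10.4f}{tail}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": "sigmoid L/(1+exp(-k(x-x0)))",
            "L": self.L,
            "k": self.k,
            "x0": self.x0,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "ci_level": self.ci_level,
            "seed": self.seed,
            "param_ci": {k: list(v) for k, v in self.param_ci.items()},
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class SigmoidRecallModel:
    """Least-squares sigmoid fit of per-record recall vs annotated-neighbor count.

    By default the model is fitted to the raw per-record points; ``binned=True``
    first collapses the data to per-count means (both conventions are in use
    for recall-saturation curves, and they answer slightly different
    questions — see the methods note).
    """

    def __init__(self, x: Sequence[float], y: Sequence[float], binned: bool = False):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if binned:
            xs = np.unique(x)
            ys = np.array([y[x == v].mean() for v in xs])
            x, y = xs, ys
        if len(np.unique(x)) < 4:
            raise ValueError("sigmoid fit requires >= 4 distinct x values")
        self.x = x
        self.y = y

    def fit(
        self,
        seed: int | None = None,
        n_boot: int = 200,
        ci_level: float = 0.95,
        ci_method: str = "basic",
    ) -> SigmoidRecallResults:
        """Fit by nonlinear least squares; CIs by seeded parametric bootstrap.

        Initialization: L = max(y), x0 = median(x), k = 1. L is constrained to
        [0, 1] (it is a recall ceiling). Bootstrap replicates regenerate the
        response as fitted-curve + Gaussian noise at the residual SD and refit.
        Parameter intervals use the basic (pivot) construction by default
        (``ci_method="percentile"`` selects raw percentiles). A constant
        response (SS_tot = 0) raises :class:`DegenerateFitError`;
        non-convergence raises it carrying the initialization and residual
        scale for diagnosis.
        """
        if ci_method not in ("basic", "percentile"):
            raise ValueError(f"unknown ci_method {ci_method!r}")
        x, y = self.x, self.y
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            raise DegenerateFitError("constant response: SS_tot = 0, R^2 undefined")
        p0 = (min(max(float(np.max(y)), 1e-6), 1.0), 1.0, float(np.median(x)))
        bounds = ([0.0, -np.inf, -np.inf], [1.0, np.inf, np.inf])
        try:
            popt, _ = curve_fit(sigmoid, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as err:
            resid_scale = float(np.std(y - sigmoid(x, *p0)))
            raise DegenerateFitError(
                f"sigmoid fit did not converge (init={p0}, "
                f"residual sd at init={resid_scale:.4g}): {err}"
            ) from err
        fitted = sigmoid(x, *popt)
        ss_res = float(np.sum((y - fitted) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        dof = max(len(x) - 3, 1)
        resid_sd = math.sqrt(ss_res / dof)

        boot = []
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            for _ in range(n_boot):
                yb = fitted + rng.normal(0.0, resid_sd, size=len(x))
                try:
                    pb, _ = curve_fit(sigmoid, x, yb, p0=popt, bounds=bounds,
                                      maxfev=20000)
                    boot.append(pb)
                except RuntimeError:
                    continue  # rare non-convergence: drop the replicate
        boot_arr = np.array(boot) if boot else None
        param_ci: dict[str, tuple[float, float]] = {}
        if boot_arr is not None and len(boot_arr) >= 20:
            alpha = (1.0 - ci_level) / 2.0
            for i, name in enumerate(("L", "k", "x0")):
                q_lo = float(np.quantile(boot_arr[:, i], alpha))
                q_hi = float(np.quantile(boot_arr[:, i], 1.0 - alpha))
                if ci_method == "basic":
                    # pivot interval 2θ̂ − q: corrects the first-order bias a
                    # percentile interval inherits from simulating at θ̂
                    param_ci[name] = (2 * popt[i] - q_hi, 2 * popt[i] - q_lo)
                else:
                    param_ci[name] = (q_lo, q_hi)
        return SigmoidRecallResults(
            L=float(popt[0]), k=float(popt[1]), x0=float(popt[2]),
            r_squared=r2, residual_sd=resid_sd, n_obs=len(x),
            ci_level=ci_level, seed=seed, param_ci=param_ci,
            boot_params=boot_arr,
        )


def fit_sigmoid(
    x: Sequence[float],
    y: Sequence[float],
    seed: int | None = None,
    n_boot: int = 200,
    binned: bool = False,
    ci_level: float = 0.95,
    ci_method: str = "basic",
) -> SigmoidRecallResults:
    """Functional wrapper: fit the recall-saturation sigmoid to (x, y) points."""
    return SigmoidRecallModel(x, y, binned=binned).fit(
        seed=seed, n_boot=n_boot, ci_level=ci_level, ci_method=ci_method
    )


def predict_recall(fit: SigmoidRecallResults, x, ci: bool = False):
    """Extrapolated recall at annotated-neighbor count ``x`` (clipped to [0, 1])."""
    return fit.predict(x, ci=ci)


def plot_curves(points: Sequence[CurvePoint], path: str | Path,
                title: str = "") -> None:
    """Render recall/precision/MAP vs annotated-neighbor bin to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [p for p in points if not p.open_ended]
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = [p.bin for p in shown]
    ax.plot(xs, [p.mean_recall for p in shown], "o-", label="recall")
    ax.plot(xs, [p.mean_precision for p in shown], "s-", label="precision")
    ax.plot(xs, [p.map for p in shown], "^-", label="MAP")
    ax.set_xlabel("annotated neighbors")
    ax.set_ylabel("fraction")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
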