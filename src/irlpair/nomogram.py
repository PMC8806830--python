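"""Points-based nomogram over a multivariate Cox model, with Harrell's
C-index and per-horizon calibration curves.

The nomogram rescales each covariate's Cox contribution to a 0-100 point
axis: a covariate at its minimum-risk observed value scores 0 points and
the covariate with the largest |beta x range| spans exactly 0-100.
Predicted survival uses the Cox relation S(t|x) = S0(t)^exp(lp(x)) with a
Breslow baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index

from .evaluate import YEAR_DAYS, km_estimate, logger


@dataclass
class NomogramModel:
    """Point tables plus the fitted Cox machinery needed for prediction."""

    covariates: list
    betas: np.ndarray
    ref_values: np.ndarray      # observed minimum-risk value per covariate
    points_per_unit: np.ndarray  # points awarded per unit of beta_j * (x - ref)
    max_span: float             # |beta x range| of the widest covariate
    horizons_days: np.ndarray
    s0_times: np.ndarray        # Breslow baseline survival at x = 0
    s0_values: np.ndarray

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.covariates].to_numpy(dtype=float) @ self.betas

    def points(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-covariate and total points for each subject."""
        out = {}
        for j, cov in enumerate(self.covariates):
            out[cov] = (
                100.0
                * self.betas[j]
                * (X[cov].to_numpy(dtype=float) - self.ref_values[j])
                / self.max_span
            )
        df = pd.DataFrame(out, index=X.index)
        df["total"] = df.sum(axis=1)
        return df

    def baseline_survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.s0_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.s0_values[idx])

    def predict_survival(self, X: pd.DataFrame, horizon_days: float) -> np.ndarray:
        s0 = self.baseline_survival_at(horizon_days)
        return s0 ** np.exp(self.linear_predictor(X))

    def survival_at_points(self, total_points, horizon_days: float) -> np.ndarray:
        """The nomogram's total-points -> survival read-out."""
        lp_ref = float(self.betas @ self.ref_values)
        lp = lp_ref + np.asarray(total_points, dtype=float) * self.max_span / 100.0
        s0 = self.baseline_survival_at(horizon_days)
        return s0 ** np.exp(lp)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "covariates": list(self.covariates),
            "betas": self.betas.tolist(),
            "ref_values": self.ref_values.tolist(),
            "points_per_unit": self.points_per_unit.tolist(),
            "max_span": self.max_span,
            "horizons_days": self.horizons_days.tolist(),
            "s0": {"times": self.s0_times.tolist(), "values": self.s0_values.tolist()},
        }, indent=1))


def build_nomogram(
    data: pd.DataFrame,
    covariates=("t_stage", "risk_score"),
    horizons_years=(1.0, 3.0, 5.0),
) -> tuple[NomogramModel, CoxPHFitter]:
    """Fit a multivariate Cox model and derive the nomogram point scales.

    ``data`` holds ``os_days``, ``event`` and the (numeric) covariates; rows
    with missing covariates are dropped.
    """
    covariates = list(covariates)
    df = data[["os_days", "event", *covariates]].dropna()
    mins = df[covariates].min().to_numpy(dtype=float)
    maxs = df[covariates].max().to_numpy(dtype=float)
    ranges = maxs - mins
    if (ranges == 0).any():
        bad = [c for c, r in zip(covariates, ranges) if r == 0]
        raise ValueError(f"zero-range covariates: {bad}")
    cph = CoxPHFitter().fit(df, "os_days", "event")
    betas = cph.params_.reindex(covariates).to_numpy()
    spans = np.abs(betas) * ranges
    max_span = float(spans.max())
    ref = np.where(betas >= 0, mins, maxs)  # the minimum-risk observed value

    s0 = cph.predict_survival_function(
        pd.DataFrame([dict.fromkeys(covariates, 0.0)])
    )[0]
    model = NomogramModel(
        covariates=covariates,
        betas=betas,
        ref_values=ref,
        points_per_unit=100.0 * betas / max_span,
        max_span=max_span,
        horizons_days=np.asarray(horizons_years, dtype=float) * YEAR_DAYS,
        s0_times=s0.index.to_numpy(dtype=float),
        s0_values=s0.to_numpy(dtype=float),
    )
    return model, cph


def harrell_c(lp, times, events) -> float:
    """Harrell's concordance for a risk score (higher score = earlier event).

    Comparable pairs: the smaller observed time belongs to an event.  Tied
    scores count 1/2.
    """
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    try:
        return float(concordance_index(times, -lp, events))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs: concordance undefined") from exc


def calibration_curve(
    model: NomogramModel,
    data: pd.DataFrame,
    horizon_days: float,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Predicted-vs-observed survival at a horizon, binned by prediction.

    Samples are binned by quantiles of predicted survival; the observed
    value per bin is the Kaplan-Meier estimate at the horizon with its
    Greenwood 95% CI.  Bins with no follow-up reaching the horizon are
    dropped (logged).
    """
    if not 1 <= n_bins <= 10:
        raise ValueError("n_bins must be in [1, 10]")
    df = data[["os_days", "event", *model.covariates]].dropna()
    if len(df) < n_bins * 10:
        raise ValueError(f"need >= {n_bins * 10} samples for {n_bins} bins")
    pred = model.predict_survival(df, horizon_days)
    bins = pd.qcut(pred, n_bins, labels=False, duplicates="drop")
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        t = df["os_days"].to_numpy()[sel]
        e = df["event"].to_numpy()[sel]
        if t.max() < horizon_days:
            logger.info("calibration_curve: dropped bin %d (no follow-up at horizon)", b)
            continue
        km = KaplanMeierFitter().fit(t, e)
        obs = float(km.predict(horizon_days))
        ci = km.confidence_interval_survival_function_
        at = ci.index[ci.index <= horizon_days]
        lo, hi = (float(ci.loc[at[-1]].iloc[0]), float(ci.loc[at[-1]].iloc[1])) if len(at) else (0.0, 1.0)
        rows.append({
            "bin": int(b),
            "n": int(sel.sum()),
            "predicted": float(pred[sel].mean()),
            "observed": obs,
            "ci_lo": lo,
            "ci_hi": hi,
        })
    return pd.DataFrame(rows).set_index("bin")


def simulate_from_model(
    model: NomogramModel, X: pd.DataFrame, rng, max_follow_days: float | None = None
) -> pd.DataFrame:
    """Draw survival data exactly from the fitted Cox model.

    Event times are generated by inverting the Breslow baseline cumulative
    hazard; times falling beyond the baseline's support are administratively
    censored at the end of follow-up.
    """
    lp = model.linear_predictor(X)
    h0 = -np.log(np.clip(model.s0_values, 1e-300, None))
    t_grid = model.s0_times
    t_max = max_follow_days if max_follow_days is not None else float(t_grid.max())
    u = rng.uniform(size=len(lp))
    target = -np.log(u) / np.exp(lp)
    idx = np.searchsorted(h0, target, side="left")
    times = np.where(idx < len(t_grid), t_grid[np.minimum(idx, len(t_grid) - 1)], np.inf)
    event = times <= t_max
    times = np.minimum(times, t_max)
    return pd.DataFrame(
        {"os_days": times, "event": event.astype(int)}, index=X.index
    )
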