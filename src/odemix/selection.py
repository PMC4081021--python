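"""Information criteria, model ranking and the delta-BIC rejection rule.

Candidate ODE-MMs (variability hypothesis x distribution assumption) are
compared by BIC with the sample size taken as the total number of
single-cell measurements pooled over all snapshots.  Following the
Kass-Raftery convention, a model is rejected when its BIC exceeds the best
model's by more than 10 (decisive evidence); the best model is labelled
"optimal", the remainder "not rejected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["bic", "aic", "SelectionTable", "selection_table", "rank_and_decide"]

DEFAULT_THRESHOLD = 10.0

COLUMNS = ["label", "m", "distribution", "ODE_const", "variability",
           "n_par", "loglik", "AIC", "BIC", "delta_BIC", "rank", "decision"]


def bic(loglik: float, n_par: int, n_obs: int) -> float:
    """-2 l + n_par * ln(n_obs); n_obs counts every cell in every snapshot."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * float(loglik) + n_par * float(np.log(n_obs))


def aic(loglik: float, n_par: int) -> float:
    """-2 l + 2 * n_par."""
    return -2.0 * float(loglik) + 2.0 * n_par


@dataclass
class SelectionTable:
    """Ranked candidate models with criteria and decisions."""

    frame: pd.DataFrame
    n_obs: int
    threshold: float

    @property
    def best(self) -> pd.Series:
        return self.frame.iloc[0]

    def decisions(self) -> dict:
        return dict(zip(self.frame["label"], self.frame["decision"]))

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def report(self) -> str:
        """Human-readable summary mirroring the printed-table column order."""
        cols = ["m", "distribution", "ODE_const", "variability", "n_par",
                "loglik", "BIC", "rank", "delta_BIC", "decision"]
        df = self.frame.sort_values("rank")[cols].copy()
        df["loglik"] = df["loglik"].map(lambda x: f"{x / 1e4:.4f}e4")
        df["BIC"] = df["BIC"].map(lambda x: f"{x / 1e4:.4f}e4")
        df["delta_BIC"] = df["delta_BIC"].map(
            lambda x: ">10" if x > 10 else f"{x:.3f}")
        return df.to_string(index=False)


def selection_table(entries, n_obs: int, threshold: float = DEFAULT_THRESHOLD
                    ) -> SelectionTable:
    """Build the ranked table from raw (label, n_par, loglik, ...) entries.

    Each entry is a mapping with at least ``label``, ``n_par`` and
    ``loglik``; optional descriptive keys ``m``, ``distribution``,
    ``ODE_const`` and ``variability`` are carried through.
    """
    if not entries:
        raise ValueError("no models to rank")
    rows = []
    for e in entries:
        row = {
            "label": e["label"],
            "m": e.get("m", np.nan),
            "distribution": e.get("distribution", ""),
            "ODE_const": e.get("ODE_const", ""),
            "variability": e.get("variability", "-"),
            "n_par": int(e["n_par"]),
            "loglik": float(e["loglik"]),
        }
        row["AIC"] = aic(row["loglik"], row["n_par"])
        row["BIC"] = bic(row["loglik"], row["n_par"], n_obs)
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values("BIC", kind="stable").reset_index(drop=True)
    df["delta_BIC"] = df["BIC"] - df["BIC"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    ties = np.isclose(df["delta_BIC"].iloc[1:], 0.0).sum() if len(df) > 1 else 0
    if ties:
        warnings.warn("BIC tie at rank 1; decisions use stable input order")
    decision = np.where(df["delta_BIC"] > threshold, "rejected", "not rejected")
    decision[0] = "optimal"
    df["decision"] = decision
    return SelectionTable(frame=df[COLUMNS], n_obs=n_obs, threshold=threshold)


def rank_and_decide(fits, n_obs: int | None = None,
                    threshold: float = DEFAULT_THRESHOLD) -> SelectionTable:
    """Rank fitted ODE-MMs; ``fits`` is a list of (spec, FitResult) pairs."""
    entries = []
    obs_counts = set()
    for spec, fit in fits:
        entries.append({
            "label": spec.label,
            "m": spec.n_subpop,
            "distribution": spec.assumption.family,
            "ODE_const": spec.assumption.constrained_stat,
            "variability": spec.hypothesis.label,
            "n_par": spec.n_parameters,
            "loglik": fit.loglik,
        })
        obs_counts.add(fit.n_obs)
    if n_obs is None:
        if len(obs_counts) != 1:
            raise ValueError("fits use different datasets; pass n_obs explicitly")
        n_obs = obs_counts.pop()
    return selection_table(entries, n_obs=n_obs, threshold=threshold)
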