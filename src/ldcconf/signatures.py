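"""Statistical signatures of Bayesian confidence.

Four curves any Bayesian-readout-like confidence measure should show:

1. mean confidence is higher on correct than on error trials;
2. the folded X-pattern — confidence rises with evidence strength on
   corrects and falls with evidence strength on errors;
3. at every evidence strength above zero, the high-confidence half of
   trials (median split) is more accurate than the low-confidence half;
4. mean confidence decreases across successive RT bins.

Evidence strength is the difficulty level (drift-rate index): that is what
an experimenter observes in real data, unlike trial-level latent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SignatureSet", "signature_curves"]


@dataclass
class SignatureSet:
    """Tidy signature curves: one row per (curve, x, group) cell with the
    across-participant mean, SEM and participant count.  Cells with no
    trials for any participant are absent (undefined), not an error."""

    curves: pd.DataFrame

    def curve(self, name: str) -> pd.DataFrame:
        return self.curves[self.curves["curve"] == name].reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return self.curves.copy()


def _aggregate(per_participant: pd.DataFrame, curve: str) -> pd.DataFrame:
    g = per_participant.groupby(["x", "group"], dropna=False)["value"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    out.insert(0, "curve", curve)
    out = out.rename(columns={"count": "n"})
    return out


def signature_curves(
    trials: pd.DataFrame,
    n_rt_bins: int = 6,
) -> SignatureSet:
    """Compute the four signature curves from a trial table.

    Median splits and RT bins are within participant; trials at the median
    rating go to the lower half (deterministic tie rule).  Curves are
    averaged across participants with SEM.
    """
    required = {"participant", "difficulty", "accuracy", "rating", "decision_rt"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")

    rows = []
    for pid, t in trials.groupby("participant"):
        rating = t["rating"].to_numpy(float)
        acc = t["accuracy"].to_numpy(int)
        diff = t["difficulty"].to_numpy(int)
        rt = t["decision_rt"].to_numpy(float)

        # 1. confidence by accuracy
        for k in (0, 1):
            if np.any(acc == k):
                rows.append((pid, "conf_by_accuracy", k, "", rating[acc == k].mean()))

        # 2. folded X: confidence by (evidence strength, accuracy)
        for d in np.unique(diff):
            for k in (0, 1):
                sel = (diff == d) & (acc == k)
                if np.any(sel):
                    rows.append((pid, "folded_x", int(d), str(k), rating[sel].mean()))

        # 3. conditional accuracy by confidence half (median split).  The
        # split uses the continuous confidence when the table carries it
        # (simulated data), because a discrete rating scale with a ceiling
        # can put the median at the top rating and empty the high half;
        # ties go to the lower half either way.
        split_var = (
            t["confidence"].to_numpy(float) if "confidence" in t.columns else rating
        )
        med = np.median(split_var)
        high = split_var > med
        for d in np.unique(diff):
            for half, sel_half in (("low", ~high), ("high", high)):
                sel = (diff == d) & sel_half
                if np.any(sel):
                    rows.append(
                        (pid, "conditional_accuracy", int(d), half, acc[sel].mean())
                    )

        # 4. confidence by RT quantile bin
        edges = np.quantile(rt, np.linspace(0, 1, n_rt_bins + 1)[1:-1])
        bins = np.searchsorted(edges, rt, side="left")
        for b in range(n_rt_bins):
            sel = bins == b
            if np.any(sel):
                rows.append((pid, "conf_by_rt_bin", int(b), "", rating[sel].mean()))

    per_part = pd.DataFrame(
        rows, columns=["participant", "curve", "x", "group", "value"]
    )
    curves = pd.concat(
        [
            _aggregate(per_part[per_part["curve"] == c], c)
            for c in per_part["curve"].unique()
        ],
        ignore_index=True,
    )
    return SignatureSet(curves=curves)
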