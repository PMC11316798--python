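"""Histidine-kinase phosphorylation and phosphotransfer kinetics.

Autophosphorylation and phosphotransfer time courses quantified by gel
densitometry follow a saturating exponential

    S(t) = dS * (1 - exp(-k t)) + S0

optionally extended to the sum of two such components with ordered rates
(k > k2).  The rate constant(s) are shared globally across replicate
traces while the amplitude dS and baseline S0 float per trace; for
phosphotransfer experiments the baselines can instead be constrained to
the signal measured at time zero.

The fit is separable: given the rates, every dS and S0 is linear, so the
outer optimisation runs over the (log) rates only.  Units of ``k`` are
the reciprocal of whatever unit the time axis uses; they are echoed from
the input, never assumed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "KineticsTrace",
    "SaturationKineticsModel",
    "SaturationResults",
    "saturation_model",
]


@dataclass
class KineticsTrace:
    """One densitometry time course.

    ``signal`` is in arbitrary counts; ``times`` must be increasing with
    t0 >= 0 and at least 4 observations.
    """

    times: np.ndarray
    signal: np.ndarray
    replicate_id: str = ""
    species: str = ""
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be equal-length 1-D arrays")
        if self.times.size < 4:
            raise ValueError("a kinetics trace needs at least 4 points")
        if not np.all(np.diff(self.times) > 0) or self.times[0] < 0:
            raise ValueError("times must be strictly increasing with t0 >= 0")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    @classmethod
    def from_csv(cls, path) -> List["KineticsTrace"]:
        """Read ``time_s,signal,replicate_id[,species]`` into traces."""
        df = pd.read_csv(path)
        missing = {"time_s", "signal", "replicate_id"} - set(df.columns)
        if missing:
            raise ValueError(f"kinetics CSV missing columns: {sorted(missing)}")
        traces = []
        for rid, grp in df.groupby("replicate_id", sort=True):
            grp = grp.sort_values("time_s")
            species = str(grp["species"].iloc[0]) if "species" in grp else ""
            traces.append(cls(grp["time_s"].to_numpy(), grp["signal"].to_numpy(),
                              replicate_id=str(rid), species=species))
        return traces


def saturation_model(delta_s, k, s0, t):
    """Saturating exponential ``dS (1 - e^{-k t}) + S0``.

    ``delta_s`` may be negative (a donor losing label during
    phosphotransfer decays from S0 toward S0 + dS).
    """
    if k <= 0:
        raise ValueError("rate constant must be positive")
    t = np.asarray(t, dtype=float)
    out = delta_s * (1.0 - np.exp(-k * t)) + s0
    return out if out.ndim else float(out)


class SaturationKineticsModel:
    """Globally shared rate(s) across replicate saturation traces.

    Parameters
    ----------
    traces : sequence of KineticsTrace
    n_components : {1, 2}
        One saturating exponential, or the sum of two with ordered rates.
    constrain_baseline : bool
        Fix each trace's S0 to its signal at t = 0 (the trace must then
        contain a t = 0 observation) and drop it from the free parameters.
    weighting : {"homoscedastic", "poisson"}
        Residual weights; "poisson" scales residuals by 1/sqrt(signal)
        for count-like densitometry noise.
    """

    def __init__(self, traces: Sequence[KineticsTrace], n_components: int = 1,
                 constrain_baseline: bool = False,
                 weighting: str = "homoscedastic"):
        if not traces:
            raise ValueError("need at least one trace")
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if weighting not in ("homoscedastic", "poisson"):
            raise ValueError("weighting must be 'homoscedastic' or 'poisson'")
        self.traces = list(traces)
        self.n_components = n_components
        self.constrain_baseline = bool(constrain_baseline)
        self.weighting = weighting
        if constrain_baseline:
            for tr in self.traces:
                if tr.times[0] != 0:
                    raise ValueError(
                        f"trace {tr.replicate_id!r} lacks a t=0 observation "
                        "required by the baseline constraint")
        if n_components == 2 and any(tr.times.size < 8 for tr in self.traces):
            import warnings
            warnings.warn("two-component fit with < 8 points per trace is "
                          "over-parameterised", stacklevel=2)
        spread = max(float(np.ptp(tr.signal)) for tr in self.traces)
        if spread == 0.0:
            raise ValueError("all traces are flat: no rate information")
        self._weights = [
            1.0 / np.sqrt(np.clip(tr.signal, 1.0, None)) if weighting == "poisson"
            else np.ones_like(tr.signal)
            for tr in self.traces
        ]

    # -- separable solve ---------------------------------------------------
    def _linear_fit(self, rates):
        """Per-trace linear solve of amplitudes (and baselines) given rates."""
        coefs, resids = [], []
        for tr, wt in zip(self.traces, self._weights):
            t, y = tr.times, tr.signal.astype(float)
            cols = [1.0 - np.exp(-k * t) for k in rates]
            if self.constrain_baseline:
                s0 = float(y[0])
                rhs = y - s0
            else:
                cols.append(np.ones_like(t))
                s0 = None
                rhs = y
            X = np.column_stack(cols) * wt[:, None]
            beta, *_ = np.linalg.lstsq(X, rhs * wt, rcond=None)
            fitted = np.column_stack(cols) @ beta + (s0 if s0 is not None else 0.0)
            coefs.append((beta, s0))
            resids.append((y - fitted) * wt)
        return coefs, resids

    def _rss(self, logk) -> float:
        _, resids = self._linear_fit(np.exp(np.atleast_1d(logk)))
        return float(sum(np.sum(r**2) for r in resids))

    def _k_grid(self, n: int = 40) -> np.ndarray:
        tmax = max(tr.times[-1] for tr in self.traces)
        tmin = min(t for tr in self.traces for t in tr.times if t > 0)
        return np.logspace(np.log10(0.05 / tmax), np.log10(20.0 / tmin), n)

    def fit(self) -> "SaturationResults":
        grid = self._k_grid()
        if self.n_components == 1:
            rss = [self._rss(np.log([k])) for k in grid]
            x0 = np.log([grid[int(np.argmin(rss))]])
        else:
            best, best_rss = None, np.inf
            for i in range(0, len(grid), 2):
                for j in range(i + 2, len(grid), 2):
                    r = self._rss(np.log([grid[j], grid[i]]))
                    if r < best_rss:
                        best_rss, best = r, np.log([grid[j], grid[i]])
            x0 = best

        def obj(logk):
            _, resids = self._linear_fit(np.exp(logk))
            return np.concatenate(resids)

        sol = optimize.least_squares(obj, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rates = np.sort(np.exp(sol.x))[::-1]  # enforce k > k2 by relabeling
        coefs, resids = self._linear_fit(rates)

        k_se = self._rate_se(rates, coefs, resids)
        n_obs = sum(tr.times.size for tr in self.traces)
        rms = float(np.sqrt(sum(np.sum(r**2) for r in resids) / n_obs))
        delta_s = np.array([beta[:self.n_components] for beta, _ in coefs])
        if self.constrain_baseline:
            s0 = np.array([s for _, s in coefs])
        else:
            s0 = np.array([beta[self.n_components] for beta, _ in coefs])
        return SaturationResults(
            k=rates, k_se=k_se, delta_s=delta_s, s0=s0,
            replicate_ids=[tr.replicate_id for tr in self.traces],
            n_components=self.n_components,
            baseline_constrained=self.constrain_baseline,
            residual_rms=rms, traces=self.traces)

    def _rate_se(self, rates, coefs, resids) -> np.ndarray:
        """SEs from the full Jacobian over rates and per-trace linear terms."""
        m = len(rates)
        R = len(self.traces)
        per = m + (0 if self.constrain_baseline else 1)
        ncol = m + R * per
        rows = sum(tr.times.size for tr in self.traces)
        J = np.zeros((rows, ncol))
        r0 = 0
        for ri, (tr, (beta, _), wt) in enumerate(zip(self.traces, coefs, self._weights)):
            t = tr.times
            nr = t.size
            rsl = slice(r0, r0 + nr)
            for mi, k in enumerate(rates):
                J[rsl, mi] = beta[mi] * t * np.exp(-k * t) * wt
            for bi in range(m):
                J[rsl, m + ri * per + bi] = (1.0 - np.exp(-rates[bi] * t)) * wt
            if not self.constrain_baseline:
                J[rsl, m + ri * per + m] = wt
            r0 += nr
        dof = max(rows - ncol, 1)
        s2 = float(sum(np.sum(r**2) for r in resids)) / dof
        jtj = J.T @ J
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
        return np.sqrt(np.clip(np.diag(cov)[:m], 0, None))


@dataclass
class SaturationResults:
    """Global saturation-kinetics fit across replicates."""

    k: np.ndarray
    k_se: np.ndarray
    delta_s: np.ndarray
    s0: np.ndarray
    replicate_ids: List[str]
    n_components: int
    baseline_constrained: bool
    residual_rms: float
    traces: List[KineticsTrace] = field(repr=False, default=None)

    def predict(self, trace_index: int, t=None) -> np.ndarray:
        tr = self.traces[trace_index]
        t = tr.times if t is None else np.asarray(t, dtype=float)
        out = np.full_like(t, self.s0[trace_index], dtype=float)
        for mi in range(self.n_components):
            out += self.delta_s[trace_index, mi] * (1.0 - np.exp(-self.k[mi] * t))
        return out

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Global saturation-kinetics fit\n")
        buf.write(f"  components: {self.n_components}   "
                  f"baseline constrained to t=0: {self.baseline_constrained}\n")
        for mi in range(self.n_components):
            label = "k " if self.n_components == 1 else f"k{mi + 1}"
            buf.write(f"  {label} = {self.k[mi]:.6g} (1/time unit of input)  "
                      f"(SE {self.k_se[mi]:.2g})\n")
        buf.write(f"  {'replicate':>12} {'dS':>12} {'S0':>12}\n")
        for rid, ds, s0 in zip(self.replicate_ids, self.delta_s, self.s0):
            ds_txt = "/".join(f"{d:.5g}" for d in ds)
            buf.write(f"  {rid:>12} {ds_txt:>12} {s0:12.5g}\n")
        buf.write(f"  residual RMS: {self.residual_rms:.4g} counts\n")
        return buf.getvalue()

    def to_report(self) -> dict:
        return {
            "k_per_time_unit": [float(v) for v in self.k],
            "k_se": [float(v) for v in self.k_se],
            "n_components": self.n_components,
            "baseline_constrained": self.baseline_constrained,
            "residual_rms": self.residual_rms,
            "replicates": [
                {"replicate_id": rid,
                 "delta_s": [float(d) for d in ds],
                 "s0": float(s0)}
                for rid, ds, s0 in zip(self.replicate_ids, self.delta_s, self.s0)
            ],
            "units_note": "rate is 1/(time unit of the input); units are "
                          "echoed from the data, never assumed",
        }
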