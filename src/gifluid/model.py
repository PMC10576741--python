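"""Model/Results interface for closed-loop fluid kinetics.

:class:`ClosedLoopStudy` is built from loop records or reconstructed volume
observations; :meth:`ClosedLoopStudy.fit` runs the full per-region analysis
(apparent absorption, real absorption, secretion, permeability, blood-flow
comparison, region comparisons) and returns a :class:`ClosedLoopResults`
carrying the estimates, bootstrap uncertainties and a ``summary()`` table.

Typical use::

    records = generate_worked_fixture()
    res = ClosedLoopStudy.from_records(records).fit()
    print(res.summary())
    res.simulate("jejunum", times=np.linspace(0, 60, 61))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import estimation, permeability as perm
from .anova import ComparisonResult, anova_tukey
from .estimation import (
    DEFAULT_T_MAX_FIT,
    RateEstimate,
    _ksec_lstsq,
    _ols_slope,
    fit_k_sec,
    fit_log_linear,
    single_point_rates,
)
from .exceptions import EstimationError, ValidationError
from .kinetics import (
    DEFAULT_S_RATIO,
    DEFAULT_V_BODY_ML,
    ModelParams,
    Trajectory,
    simulate,
)
from .volumes import (
    DEFAULT_RECOVERY_THRESHOLD,
    DEFAULT_SURFACE_AREA_CM2,
    MARKER_FD4,
    MARKER_TRACER,
    qc_filter,
    records_to_volumes,
    summarize_timecourse,
)

__all__ = ["StudyConstants", "ClosedLoopStudy", "ClosedLoopResults"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConstants:
    """Physiological and design constants of the closed-loop analysis."""

    v_body_ml: float = DEFAULT_V_BODY_ML
    surface_area_cm2: float = DEFAULT_SURFACE_AREA_CM2
    s_ratio: float = DEFAULT_S_RATIO
    v_lumen_ml: float = 1.0
    t_max_fit_min: float = DEFAULT_T_MAX_FIT
    recovery_threshold: float = DEFAULT_RECOVERY_THRESHOLD
    q_portal_ml_per_min_per_kg: float = perm.DEFAULT_Q_PORTAL_ML_MIN_KG
    villous_fraction: float = perm.DEFAULT_VILLOUS_FRACTION
    body_mass_kg: float = perm.DEFAULT_BODY_MASS_KG
    length_fraction: float = DEFAULT_S_RATIO
    flow_limited_threshold: float = 0.5

    def validate(self) -> None:
        for name, val in asdict(self).items():
            if not val > 0:
                raise ValidationError(f"{name} must be > 0, got {val}")
        for name in ("villous_fraction", "length_fraction", "s_ratio",
                     "recovery_threshold"):
            if getattr(self, name) > 1:
                raise ValidationError(f"{name} must be in (0, 1]")


class ClosedLoopStudy:
    """Closed-loop fluid kinetics model bound to one study's observations.

    Parameters
    ----------
    volumes : DataFrame
        Volume observations (one row per animal) with columns
        ``animal_id, region, marker, time_min, volume_ml,
        remaining_fraction``.
    constants : StudyConstants
    qc : dict, optional
        QC bookkeeping (record counts, exclusion reasons) carried into the
        report.
    """

    def __init__(
        self,
        volumes: pd.DataFrame,
        constants: StudyConstants = StudyConstants(),
        qc: dict | None = None,
    ):
        constants.validate()
        required = {"animal_id", "region", "marker", "time_min",
                    "volume_ml", "remaining_fraction"}
        missing = required - set(volumes.columns)
        if missing:
            raise ValidationError(f"volumes frame missing column(s) {sorted(missing)}")
        if volumes.empty:
            raise ValidationError("no volume observations supplied")
        self.volumes = volumes.reset_index(drop=True)
        self.constants = constants
        self.qc = qc or {}

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        constants: StudyConstants = StudyConstants(),
        surface_area_cm2: float | dict | None = None,
    ) -> "ClosedLoopStudy":
        """Build from raw loop records: QC-filter, then reconstruct volumes."""
        included, excluded = qc_filter(records, constants.recovery_threshold)
        if included.empty:
            raise ValidationError("all records excluded by QC")
        s = surface_area_cm2 if surface_area_cm2 is not None else constants.surface_area_cm2
        volumes = records_to_volumes(included, surface_area_cm2=s)
        reasons = (
            dict(excluded["exclusion_reason"].value_counts())
            if len(excluded)
            else {}
        )
        qc = {
            "n_records_in": int(len(records)),
            "n_included": int(len(included)),
            "n_excluded": int(len(excluded)),
            "exclusion_reasons": {k: int(v) for k, v in reasons.items()},
        }
        return cls(volumes, constants=constants, qc=qc)

    @classmethod
    def from_csv(cls, path, constants: StudyConstants = StudyConstants()) -> "ClosedLoopStudy":
        from .io import read_records

        return cls.from_records(read_records(path), constants=constants)

    @property
    def regions(self) -> list[str]:
        return sorted(self.volumes["region"].unique())

    def model_params(self, k_abs: float, k_sec: float) -> ModelParams:
        c = self.constants
        return ModelParams(
            k_abs=k_abs, k_sec=k_sec, v_body=c.v_body_ml,
            s_ratio=c.s_ratio, v0=c.v_lumen_ml,
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        t_max: float | None = None,
        n_boot: int = 0,
        seed: int = 0,
        pin_intercept: bool = False,
        weighted: bool = False,
    ) -> "ClosedLoopResults":
        """Fit all rate constants per region.

        Per region: ``k_abs_app`` by log-linear regression on FD-4 remaining
        fractions (t <= ``t_max``), ``k_abs`` likewise on tracer fractions,
        and ``k_sec`` by bounded least squares of the kinetic closed form on
        FD-4 volumes with ``k_abs`` fixed at the tracer estimate.  With
        ``n_boot`` >= 100, a stratified animal-level bootstrap supplies SEs
        and 95% percentile CIs; the ``k_sec`` resamples re-estimate
        ``k_abs`` jointly so its uncertainty is propagated.  ``weighted``
        weights the k_sec residuals by inverse per-time variance of the
        observed volumes.
        """
        c = self.constants
        t_max = c.t_max_fit_min if t_max is None else float(t_max)
        estimates: dict[str, dict[str, RateEstimate]] = {}
        errors: list[dict] = []
        for region in self.regions:
            sub = self.volumes[self.volumes["region"] == region]
            fd4 = sub[sub["marker"] == MARKER_FD4]
            tracer = sub[sub["marker"] == MARKER_TRACER]
            reg: dict[str, RateEstimate] = {}
            try:
                if not fd4.empty:
                    reg["k_abs_app"] = fit_log_linear(
                        fd4, t_max=t_max, pin_intercept=pin_intercept,
                        parameter="k_abs_app", region=region,
                    )
                if not tracer.empty:
                    reg["k_abs"] = fit_log_linear(
                        tracer, t_max=t_max, pin_intercept=pin_intercept,
                        parameter="k_abs", region=region,
                    )
                if "k_abs" in reg and not fd4.empty:
                    weights = self._ksec_weights(fd4) if weighted else None
                    reg["k_sec"] = fit_k_sec(
                        fd4,
                        k_abs=reg["k_abs"].estimate,
                        params=self.model_params(reg["k_abs"].estimate, 0.0),
                        weights=weights,
                        region=region,
                    )
            except EstimationError as exc:
                errors.append({"region": region, "error": str(exc)})
                log.warning("fit failed for region %s: %s", region, exc)
            if n_boot:
                self._joint_bootstrap(
                    reg, fd4, tracer, t_max, n_boot, seed, pin_intercept, region
                )
            estimates[region] = reg

        permeability = {}
        blood_flow = {}
        for region, reg in estimates.items():
            if "k_abs" in reg:
                pr = perm.permeability_for_region(
                    region, reg["k_abs"].estimate,
                    v_lumen=c.v_lumen_ml, s=c.surface_area_cm2,
                )
                permeability[region] = pr
                blood_flow[region] = perm.villous_blood_flow(
                    q_portal=c.q_portal_ml_per_min_per_kg,
                    fraction=c.villous_fraction,
                    body_mass=c.body_mass_kg,
                    length_fraction=c.length_fraction,
                    cl_abs=pr.cl_abs_ml_per_min,
                    limited_threshold=c.flow_limited_threshold,
                )

        comparisons = self._region_comparisons(t_max)
        return ClosedLoopResults(
            model=self,
            estimates=estimates,
            permeability=permeability,
            blood_flow=blood_flow,
            comparisons=comparisons,
            errors=errors,
            settings={
                "t_max_fit_min": t_max,
                "n_boot": n_boot,
                "seed": seed,
                "pin_intercept": pin_intercept,
                "weighted": weighted,
            },
        )

    @staticmethod
    def _ksec_weights(fd4: pd.DataFrame) -> np.ndarray:
        """Inverse per-time variance weights for the k_sec residuals."""
        var = fd4.groupby("time_min")["volume_ml"].transform(
            lambda x: x.var(ddof=1) if len(x) > 1 else np.nan
        )
        v = var.to_numpy(dtype=float)
        fallback = np.nanmean(v) if np.isfinite(v).any() else 1.0
        v = np.where(np.isfinite(v) & (v > 0), v, fallback if fallback > 0 else 1.0)
        return 1.0 / v

    def _joint_bootstrap(
        self,
        reg: dict[str, RateEstimate],
        fd4: pd.DataFrame,
        tracer: pd.DataFrame,
        t_max: float,
        n_boot: int,
        seed: int,
        pin_intercept: bool,
        region: str,
    ) -> None:
        """Animal-level bootstrap, stratified by time within each marker arm.

        Each resample redraws ``n - 1`` animals with replacement within every
        time stratum of both arms (the n-of-n bootstrap underestimates
        within-stratum variance), refits k_abs_app / k_abs by log-linear OLS
        and k_sec by exact 1-D least squares with the resampled k_abs — so
        the k_abs uncertainty propagates into the k_sec interval — and the
        spread of the resampled estimates yields the SE and an expanded
        percentile 95% CI (t-calibrated tails for the small residual df).
        """
        if n_boot < 100:
            raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
        rng = np.random.default_rng(seed)
        c = self.constants

        def _arrays(df: pd.DataFrame, col: str, logscale: bool):
            t = df["time_min"].to_numpy(dtype=float)
            y = df[col].to_numpy(dtype=float)
            keep = (t > 0) & (t <= t_max) & (y > 0) if logscale else np.ones(t.size, bool)
            t, y = t[keep], y[keep]
            strata = [np.flatnonzero(t == u) for u in np.unique(t)]
            return t, (np.log(y) if logscale else y), strata

        boots: dict[str, list[float]] = {k: [] for k in ("k_abs_app", "k_abs", "k_sec")}
        tr = _arrays(tracer, "remaining_fraction", True) if "k_abs" in reg else None
        fa = _arrays(fd4, "remaining_fraction", True) if "k_abs_app" in reg else None
        fv = None
        if "k_sec" in reg:
            t = fd4["time_min"].to_numpy(dtype=float)
            v = fd4["volume_ml"].to_numpy(dtype=float)
            fv = (t, v, [np.flatnonzero(t == u) for u in np.unique(t)])

        def _resample(strata):
            return np.concatenate(
                [s[rng.integers(0, s.size, max(s.size - 1, 1))] for s in strata]
            )

        for _ in range(n_boot):
            k_abs_b = None
            if tr is not None:
                idx = _resample(tr[2])
                slope, _, _, _ = _ols_slope(tr[0][idx], tr[1][idx], pin_intercept)
                k_abs_b = -slope
                boots["k_abs"].append(k_abs_b)
            if fa is not None:
                idx = _resample(fa[2])
                slope, _, _, _ = _ols_slope(fa[0][idx], fa[1][idx], pin_intercept)
                boots["k_abs_app"].append(-slope)
            if fv is not None and k_abs_b is not None and k_abs_b > 0:
                idx = _resample(fv[2])
                boots["k_sec"].append(
                    _ksec_lstsq(
                        fv[0][idx], fv[1][idx], k_abs_b,
                        c.v_body_ml, c.s_ratio, c.v_lumen_ml,
                    )
                )

        # expanded-percentile CIs need the estimator's effective df, which the
        # stratum heteroscedasticity (variance growing with time) pulls far
        # below the nominal residual df
        def _slope_df(arrs):
            t, y, _ = arrs
            if pin_intercept:
                coef = t / float(np.dot(t, t))
            else:
                tc = t - t.mean()
                coef = tc / float(np.dot(tc, tc))
            return estimation.satterthwaite_df(t, y, coef)

        dfs = {
            "k_abs": _slope_df(tr) if tr else None,
            "k_abs_app": _slope_df(fa) if fa else None,
            "k_sec": None,
        }
        if fv is not None and "k_abs" in reg:
            t, v, _ = fv
            decay = np.exp(-reg["k_abs"].estimate * t)
            b_coef = (c.v_body_ml * c.s_ratio / reg["k_abs"].estimate) * (1.0 - decay)
            dfs["k_sec"] = estimation.satterthwaite_df(
                t, v, b_coef / float(np.dot(b_coef, b_coef))
            )
        for name, values in boots.items():
            if name not in reg or not values:
                continue
            est = np.asarray(values)
            lo, hi = np.percentile(est, estimation.expanded_percentiles(dfs[name]))
            reg[name].se = float(est.std(ddof=1))
            reg[name].ci_low = float(lo)
            reg[name].ci_high = float(hi)
            reg[name].method += f" + bootstrap({len(est)})"

    def _region_comparisons(self, t_max: float) -> dict[str, ComparisonResult]:
        """ANOVA + Tukey–Kramer across regions on per-animal rate constants."""
        out: dict[str, ComparisonResult] = {}
        for name, marker in (("k_abs", MARKER_TRACER), ("k_abs_app", MARKER_FD4)):
            groups = {}
            for region in self.regions:
                sub = self.volumes[
                    (self.volumes["region"] == region)
                    & (self.volumes["marker"] == marker)
                ]
                k = single_point_rates(sub, t_max=t_max)
                if len(k) >= 2:
                    groups[region] = k.to_numpy()
            if len(groups) >= 2:
                out[f"{name}_across_regions"] = anova_tukey(groups)
        return out


class ClosedLoopResults:
    """Fit results: rate constants, permeabilities, comparisons, reports."""

    def __init__(self, model, estimates, permeability, blood_flow,
                 comparisons, errors, settings):
        self.model = model
        self.estimates = estimates
        self.permeability = permeability
        self.blood_flow = blood_flow
        self.comparisons = comparisons
        self.errors = errors
        self.settings = settings

    # -- accessors ------------------------------------------------------
    def rate(self, region: str, parameter: str) -> RateEstimate:
        try:
            return self.estimates[region][parameter]
        except KeyError:
            raise KeyError(f"no {parameter} estimate for region {region!r}") from None

    def k_abs(self, region: str) -> float:
        return self.rate(region, "k_abs").estimate

    def k_sec(self, region: str) -> float:
        return self.rate(region, "k_sec").estimate

    def k_abs_app(self, region: str) -> float:
        return self.rate(region, "k_abs_app").estimate

    @property
    def estimates_frame(self) -> pd.DataFrame:
        rows = [
            est.to_dict()
            for reg in self.estimates.values()
            for est in reg.values()
        ]
        return pd.DataFrame(rows)

    def table1_frame(self, sig: int = 3) -> pd.DataFrame:
        """Clearance/permeability table: CL_abs (mL/min), P_eff (x1e-4 cm/s)."""
        rows = []
        for region, pr in self.permeability.items():
            rows.append(
                {
                    "region": region,
                    "cl_abs_ml_per_min": perm.round_sig(pr.cl_abs_ml_per_min, sig),
                    "p_eff_1e4_cm_per_s": perm.round_sig(pr.p_eff_cm_per_s * 1e4, sig),
                }
            )
        return pd.DataFrame(rows)

    # -- simulation / plotting -----------------------------------------
    def simulate(self, region: str, times, mode: str = "constant_body") -> Trajectory:
        """Simulate the fitted kinetics for one region (decomposed trajectory)."""
        p = self.model.model_params(self.k_abs(region), self.k_sec(region))
        return simulate(p, times, mode=mode)

    def plot_timecourse(self, region: str, ax=None):
        """Observed remaining fractions with the fitted model curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        vols = self.model.volumes
        sub = vols[vols["region"] == region]
        for marker, color, label in (
            (MARKER_FD4, "tab:blue", "FD-4 (total fluid)"),
            (MARKER_TRACER, "tab:red", "tracer (ingested water)"),
        ):
            m = sub[sub["marker"] == marker]
            if m.empty:
                continue
            ax.plot(m["time_min"], m["remaining_fraction"], "o",
                    color=color, alpha=0.5, label=label)
        try:
            t = np.linspace(0, float(sub["time_min"].max()), 200)
            traj = self.simulate(region, t)
            v0 = self.model.constants.v_lumen_ml
            ax.plot(t, traj.v_gi / v0, "-", color="tab:blue")
            ax.plot(t, traj.v_ingested / v0, "--", color="tab:red")
        except KeyError:
            pass
        ax.set_xlabel("time (min)")
        ax.set_ylabel("remaining fraction")
        ax.set_title(region)
        ax.legend(fontsize=8)
        return ax

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table of the fitted study."""
        lines = []
        c = self.model.constants
        lines.append("Closed-loop fluid kinetics — fit summary")
        lines.append("=" * 72)
        lines.append(
            f"constants: V_body={c.v_body_ml} mL  S={c.surface_area_cm2} cm^2  "
            f"S/S_sum={c.s_ratio:.5f}  V_lumen={c.v_lumen_ml} mL  "
            f"t_max={self.settings['t_max_fit_min']:g} min"
        )
        if self.model.qc:
            q = self.model.qc
            lines.append(
                f"QC: {q.get('n_included', '?')}/{q.get('n_records_in', '?')} records "
                f"included; excluded: {q.get('exclusion_reasons', {})}"
            )
        lines.append("-" * 72)
        hdr = f"{'region':<10}{'parameter':<12}{'estimate':>12}{'SE':>12}{'95% CI':>24}{'n':>4}"
        lines.append(hdr)
        for region in sorted(self.estimates):
            for name in ("k_abs_app", "k_abs", "k_sec"):
                if name not in self.estimates[region]:
                    continue
                e = self.estimates[region][name]
                se = f"{e.se:.3e}" if e.se is not None else "-"
                ci = (
                    f"[{e.ci_low:.3e}, {e.ci_high:.3e}]"
                    if e.ci_low is not None
                    else "-"
                )
                lines.append(
                    f"{region:<10}{name:<12}{e.estimate:>12.4e}{se:>12}{ci:>24}{e.n:>4}"
                )
        if self.permeability:
            lines.append("-" * 72)
            lines.append(f"{'region':<10}{'CL_abs (mL/min)':>16}{'P_eff (x1e-4 cm/s)':>20}")
            for region in sorted(self.permeability):
                pr = self.permeability[region]
                lines.append(
                    f"{region:<10}{perm.round_sig(pr.cl_abs_ml_per_min):>16g}"
                    f"{perm.round_sig(pr.p_eff_cm_per_s * 1e4):>20g}"
                )
        if self.blood_flow:
            any_bf = next(iter(self.blood_flow.values()))
            lines.append("-" * 72)
            lines.append(
                f"villous flow: Q_villi={any_bf.q_villi_ml_per_min_per_kg:.3g} mL/min/kg, "
                f"loop Q_villi={any_bf.q_villi_loop_ml_per_min:.3f} mL/min"
            )
            for region in sorted(self.blood_flow):
                bf = self.blood_flow[region]
                lines.append(
                    f"  {region:<10} CL_abs/Q_villi = {bf.cl_over_q_villi:.3f} "
                    f"-> {bf.classification}"
                )
        for key, comp in self.comparisons.items():
            lines.append("-" * 72)
            lines.append(
                f"{key}: F={comp.f_stat:.4g}, p={comp.p_value:.4g}"
                + (" (no variance)" if comp.no_variance else "")
            )
            for row in comp.pairwise.itertuples():
                lines.append(
                    f"  {row.group1} vs {row.group2}: "
                    f"p_adj={row.p_adj:.4g} {row.marker}"
                )
        if self.errors:
            lines.append("-" * 72)
            for err in self.errors:
                lines.append(f"ERROR [{err['region']}]: {err['error']}")
        return "\n".join(lines)

    def timecourse_summary(self) -> pd.DataFrame:
        return summarize_timecourse(self.model.volumes)

    def to_report(self) -> dict:
        """Nested report dict (units in key names; JSON-serialisable)."""
        return {
            "constants": asdict(self.model.constants),
            "settings": self.settings,
            "qc": self.model.qc,
            "estimates": {
                region: {name: est.to_dict() for name, est in reg.items()}
                for region, reg in self.estimates.items()
            },
            "permeability": {
                region: pr.to_dict() for region, pr in self.permeability.items()
            },
            "blood_flow": {
                region: bf.to_dict() for region, bf in self.blood_flow.items()
            },
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "timecourse_summary": self.timecourse_summary().to_dict(orient="records"),
            "errors": self.errors,
        }
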