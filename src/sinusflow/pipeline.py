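"""End-to-end orchestration: generate/load -> calibrate -> sweep -> fit
-> curl -> ICP scenario -> report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .geometry import FluidProperties, VenousTree
from .hemodynamics import calibrate
from .icp import IIHCriteria, proportion_above, required_venous_drop
from .sweep import (
    DEFAULT_FLOW_GRID,
    PressureFlowCurve,
    QuadraticFit,
    fit_quadratic,
    linear_vs_quadratic,
    sweep,
    threshold_flow,
)
from .synthetic import (
    CohortSpec,
    SurrogateSpec,
    generate_cohort,
    generate_referral_cohort_flows,
    generate_surrogate,
)
from .units import ml_min_to_m3_s, mmhg_to_pa
from .vorticity import curl_pressure_correlation

logger = logging.getLogger("sinusflow")

__all__ = ["RunConfig", "run_pipeline", "plot_pressure_flow"]

# published operating anchors used for loss calibration
CALIBRATION_Q_ML_MIN = 620.0
CALIBRATION_DROP_MMHG = 4.5
HYPEREMIA_FACTOR = 1.35
COHORT_FLOW_THRESHOLD = 1500.0


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults reproduce the study constants: 200-2000 mL/min sweep in
    steps of 200, straight-sinus fraction 0.30 of SSS flow, blood at
    1055 kg/m^3 and 0.0035 Pa.s, and the paediatric hypertension
    criteria. Everything is overridable from YAML/JSON.
    """

    out_dir: str = "sinusflow_out"
    geometry_paths: list[str] = field(default_factory=list)
    n_patients: int = 5
    seed: int = 0
    flows: list[float] = field(default_factory=lambda: list(DEFAULT_FLOW_GRID))
    straight_fraction: float = 0.30
    total_inflow: bool = True
    density: float = 1055.0
    viscosity: float = 0.0035
    calibrate_to_anchor: bool = True
    reference_q_ml_min: float = CALIBRATION_Q_ML_MIN
    reference_drop_mmhg: float = CALIBRATION_DROP_MMHG
    zero_intercept: bool = True
    criteria: IIHCriteria = field(default_factory=IIHCriteria)
    hyperemia_factor: float = HYPEREMIA_FACTOR
    cohort_flow_threshold: float = COHORT_FLOW_THRESHOLD
    surrogate: SurrogateSpec | None = None
    make_plot: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        for key in d:
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
        if "criteria" in d and isinstance(d["criteria"], dict):
            try:
                d["criteria"] = IIHCriteria(**d["criteria"])
            except TypeError as exc:
                raise ConfigError(f"invalid 'criteria' block: {exc}") from exc
        if "surrogate" in d and isinstance(d["surrogate"], dict):
            try:
                d["surrogate"] = SurrogateSpec(**d["surrogate"])
            except TypeError as exc:
                raise ConfigError(f"invalid 'surrogate' block: {exc}") from exc
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0.0 <= self.straight_fraction < 1.0):
            raise ConfigError("straight_fraction: must be in [0, 1)")
        if self.density <= 0:
            raise ConfigError("density: must be positive")
        if self.viscosity <= 0:
            raise ConfigError("viscosity: must be positive")
        if not self.flows or any(q <= 0 for q in self.flows):
            raise ConfigError("flows: must be non-empty and positive")
        if self.n_patients < 1:
            raise ConfigError("n_patients: must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def fluid(self) -> FluidProperties:
        return FluidProperties(self.density, self.viscosity)


def _load_or_generate_trees(config: RunConfig) -> list[VenousTree]:
    if config.geometry_paths:
        return [VenousTree.from_json(p) for p in config.geometry_paths]
    spec = CohortSpec(n_patients=config.n_patients, seed=config.seed)
    return generate_cohort(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``. Returns the summary dictionary that is also
    written to ``summary.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fluid = config.fluid()
    flows = np.asarray(config.flows, dtype=float)

    trees = _load_or_generate_trees(config)
    logger.info("loaded %d venous trees (seed=%d)", len(trees), config.seed)

    if config.calibrate_to_anchor:
        trees = [
            calibrate(
                t,
                ml_min_to_m3_s(config.reference_q_ml_min),
                mmhg_to_pa(config.reference_drop_mmhg),
                config.straight_fraction,
                fluid,
                total_inflow=config.total_inflow,
            )
            for t in trees
        ]
        logger.info(
            "calibrated all trees to %.0f mL/min -> %.2f mmHg",
            config.reference_q_ml_min, config.reference_drop_mmhg,
        )

    curves: list[PressureFlowCurve] = []
    fits: list[QuadraticFit] = []
    for tree in trees:
        curve = sweep(tree, flows, config.straight_fraction, fluid,
                      total_inflow=config.total_inflow)
        curve.to_csv(out / f"curve_{tree.patient_id}.csv")
        tree.to_json(out / f"tree_{tree.patient_id}.json")
        fit = fit_quadratic(curve, zero_intercept=config.zero_intercept)
        curves.append(curve)
        fits.append(fit)

    req_drop = required_venous_drop(config.criteria)
    fit_rows = []
    for fit in fits:
        q_star = threshold_flow(fit, req_drop, max_flow=float(flows.max()))
        fit_rows.append(
            {**fit.to_dict(), "threshold_flow_mL_min":
             (None if not np.isfinite(q_star) else q_star)}
        )
    with open(out / "fits.json", "w") as fh:
        json.dump(fit_rows, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # surrogate curl series and curl-pressure correlations
    surr_spec = config.surrogate or SurrogateSpec(
        flows=flows, n_patients=config.n_patients, seed=config.seed
    )
    surrogate = generate_surrogate(surr_spec)
    curl_corrs = [
        curl_pressure_correlation(p.curls, p.curve.drops) for p in surrogate
    ]
    pd.DataFrame(
        {
            "patient": [p.curve.patient_id for p in surrogate],
            "curl_pressure_r": curl_corrs,
        }
    ).to_csv(out / "curl_correlations.csv", index=False)

    # ICP / hyperemia scenario
    mean_fit = QuadraticFit(
        a=float(np.mean([f.a for f in fits])),
        b=float(np.mean([f.b for f in fits])),
        intercept=float(np.mean([f.intercept for f in fits])),
        r=float(np.mean([f.r for f in fits])),
        r2=float(np.mean([f.r2 for f in fits])),
        patient_id="cohort-mean",
    )
    comparison = linear_vs_quadratic(
        config.criteria.baseline_drop, config.hyperemia_factor, mean_fit,
        required_delta=config.criteria.required_delta,
    )
    cohort_flows = generate_referral_cohort_flows(seed=config.seed)
    count, total, percent = proportion_above(cohort_flows, config.cohort_flow_threshold)

    summary = {
        "n_patients": len(trees),
        "seed": config.seed,
        "flow_grid_mL_min": [float(q) for q in flows],
        "required_venous_drop_mmHg": req_drop,
        "fits": fit_rows,
        "min_fit_pearson_r": float(min(f.r for f in fits)),
        "curl_pressure_correlations": curl_corrs,
        "min_curl_pressure_r": float(min(curl_corrs)),
        "hyperemia_comparison": comparison.to_dict(),
        "cohort_fraction_above_threshold": {
            "count": count, "total": total, "percent": percent,
            "threshold_mL_min": config.cohort_flow_threshold,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_text_report(out / "summary.txt", summary)

    if config.make_plot:
        plot_pressure_flow(curves, fits, req_drop, out / "pressure_flow.png")

    logger.info("report bundle written to %s", out)
    return summary


def _write_text_report(path: Path, s: dict) -> None:
    h = s["hyperemia_comparison"]
    c = s["cohort_fraction_above_threshold"]
    lines = [
        "Cerebral venous sinus pressure-flow analysis",
        "=" * 44,
        f"patients: {s['n_patients']}   seed: {s['seed']}",
        f"flow grid (mL/min): {', '.join(f'{q:g}' for q in s['flow_grid_mL_min'])}",
        "",
        "Quadratic fits dP = a*Q + b*Q^2 (mmHg, mL/min):",
    ]
    for f in s["fits"]:
        q = f["threshold_flow_mL_min"]
        qtxt = f"{q:.0f} mL/min" if q is not None else "not reached"
        lines.append(
            f"  {f['patient_id']}: a={f['a_mmHg_per_mL_min']:.3e} "
            f"b={f['b_mmHg_per_mL_min_sq']:.3e} r={f['pearson_r']:.4f} "
            f"IIH threshold ({s['required_venous_drop_mmHg']:.1f} mmHg) at {qtxt}"
        )
    lines += [
        f"minimum trend-line correlation r: {s['min_fit_pearson_r']:.4f}",
        f"minimum curl-pressure correlation r: {s['min_curl_pressure_r']:.4f}",
        "",
        f"Hyperemia scenario (x{h['hyperemia_factor']:.2f} flow on "
        f"{h['baseline_drop_mmHg']:.1f} mmHg baseline):",
        f"  linear (constant R_ven) increase: {h['linear_increase_mmHg']:.1f} mmHg "
        f"(exceeds +{h['required_delta_mmHg']:.1f}? {h['linear_exceeds_required']})",
        f"  quadratic-model increase:        {h['quadratic_increase_mmHg']:.1f} mmHg "
        f"(exceeds +{h['required_delta_mmHg']:.1f}? {h['quadratic_exceeds_required']})",
        "",
        f"Referral cohort: {c['count']} of {c['total']} flows above "
        f"{c['threshold_mL_min']:.0f} mL/min ({c['percent']}%)",
        "",
    ]
    path.write_text("\n".join(lines))


def plot_pressure_flow(curves, fits, threshold_drop: float, path) -> None:
    """Pressure-drop vs flow figure: per-patient points and quadratic
    trend lines, the hypertension threshold, and the constant-resistance
    reference line anchored at the calibration point."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    qq = np.linspace(0, max(float(c.flows.max()) for c in curves), 200)
    for curve, fit in zip(curves, fits):
        pts = ax.plot(curve.flows, curve.drops, "o", ms=4,
                      label=f"{curve.patient_id}")
        ax.plot(qq, fit.predict(qq), "-", lw=1, color=pts[0].get_color())
    ax.axhline(threshold_drop, color="red", lw=1.5,
               label=f"IIH threshold {threshold_drop:.1f} mmHg")
    r_lin = CALIBRATION_DROP_MMHG / CALIBRATION_Q_ML_MIN
    ax.plot(qq, r_lin * qq, "k-", lw=1.5, label="constant-resistance model")
    ax.set_xlabel("total venous inflow (mL/min)")
    ax.set_ylabel("SSS to IJV pressure drop (mmHg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
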