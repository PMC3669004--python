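"""End-to-end pipeline: data or simulation -> fit -> rates -> bias
decomposition -> identity audit -> agreement report.

``run_pipeline`` is the library entry point the CLI wraps.  It writes
``rates.csv``, ``bias.csv``, ``audit.json`` and ``report.json`` into the
output directory and returns everything in memory as well.  Hard
invariant violations (a ``Csap``/``Cap`` outside ``[0, p/dt]``, a
plastochrone bias outside its bounds) are collected rather than raised;
the CLI turns them into a nonzero exit status.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import fit_allometry, method_comparison_report, plot_rate_series
from .bias import AuditReport, campaign_bias, identity_audit, shoot_decomposition
from .estimators import campaign_rates
from .exceptions import EelgrassError, MissingThirdLeafError, ValidationError
from .io import RunOptions, load_config, read_leaf_table
from .simulate import SimulationConfig, simulate_campaigns
from .types import AllometricParams, Campaign, CampaignBias, CampaignRates, FitResult

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("eelgrass_allometry")

_REL_TOL = 1e-9


@dataclass
class PipelineResult:
    params: AllometricParams
    fit: Optional[FitResult]
    rates: list[CampaignRates]
    biases: list[CampaignBias]
    audits: list[AuditReport]
    table: pd.DataFrame
    report: Optional[object]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _check_invariants(camp, rates, decomps, bias, violations: list[str]) -> None:
    scale = max(abs(rates.lgp), 1e-12)
    ratio = rates.p / rates.delta_t
    for d in decomps:
        if not (-_REL_TOL <= d.csap <= ratio * (1 + _REL_TOL) + _REL_TOL):
            violations.append(
                f"{camp.date}: Csap={d.csap:.6g} outside [0, p/dt={ratio:.6g}] "
                f"(shoot {d.shoot_id})"
            )
    if not (-_REL_TOL <= bias.cap <= ratio * (1 + _REL_TOL) + _REL_TOL):
        violations.append(f"{camp.date}: Cap={bias.cap:.6g} outside [0, p/dt={ratio:.6g}]")
    slack = 1e-9 * scale
    if not (bias.blap - slack <= bias.bp_allometric <= bias.bp_upper + slack):
        violations.append(
            f"{camp.date}: allometric Bp={bias.bp_allometric:.6g} outside bounds "
            f"[{bias.blap:.6g}, {bias.bp_upper:.6g}]"
        )


def run_pipeline(
    config_path=None,
    data_path=None,
    sidecar_path=None,
    simulate: bool = False,
    out_dir=None,
    seed: Optional[int] = None,
    config: Optional[SimulationConfig] = None,
    options: Optional[RunOptions] = None,
) -> PipelineResult:
    """Run the full analysis.

    Either ``simulate=True`` (campaigns generated from the simulation
    config) or ``data_path``+``sidecar_path`` (CSV input), never both.
    ``seed`` overrides the config seed.  ``out_dir=None`` skips writing.
    """
    if simulate and data_path is not None:
        raise ValidationError("pass either a data file or --simulate, not both")
    if not simulate and data_path is None:
        raise ValidationError("one of data_path or simulate is required")

    if config is None or options is None:
        cfg, opts = load_config(config_path)
        config = config if config is not None else cfg
        options = options if options is not None else opts
    if seed is not None:
        from dataclasses import replace
        config = replace(config, seed=seed)

    if simulate:
        campaigns = [s.campaign for s in simulate_campaigns(config)]
    else:
        if sidecar_path is None:
            raise ValidationError("CSV input needs both data_path and sidecar_path")
        campaigns = read_leaf_table(data_path, sidecar_path)
    if not campaigns:
        raise ValidationError("no campaigns to analyse")

    # allometric parameters: fitted from retrieval leaves, or from config
    fit = None
    if options.params_source == "fit":
        lengths, weights = [], []
        for camp in campaigns:
            for shoot in camp.shoots:
                for leaf in shoot.leaves:
                    if leaf.length_end > 0 and leaf.dry_weight_end > 0:
                        lengths.append(leaf.length_end)
                        weights.append(leaf.dry_weight_end)
        fit = fit_allometry(lengths, weights)
        params = fit.params
    else:
        params = config.true_params

    rates_list: list[CampaignRates] = []
    bias_list: list[CampaignBias] = []
    audit_list: list[AuditReport] = []
    violations: list[str] = []
    for camp in campaigns:
        rates = campaign_rates(camp, params, marking_mode=options.marking_mode)
        decomps = []
        for shoot in camp.shoots:
            try:
                decomps.append(shoot_decomposition(shoot, params, rates.p, rates.delta_t))
            except MissingThirdLeafError:
                continue
        bias = campaign_bias(camp, rates, decomps)
        audit = identity_audit(camp, params, rates=rates)
        _check_invariants(camp, rates, decomps, bias, violations)
        rates_list.append(rates)
        bias_list.append(bias)
        audit_list.append(audit)

    dates = [c.date for c in campaigns]
    report = None
    if all(r.lg is not None for r in rates_list) and len(rates_list) >= 3:
        report, table = method_comparison_report(rates_list, bias_list, dates=dates)
        log.info(
            "bias ordering Bm < Ba < Bp holds on %.0f%% of campaigns",
            100 * report.bias_ordering_fraction,
        )
    else:
        table = pd.DataFrame(
            {
                "date": dates,
                "lgm": [r.lgm for r in rates_list],
                "lga": [r.lga for r in rates_list],
                "lgp": [r.lgp for r in rates_list],
                "p": [r.p for r in rates_list],
                "delta_t": [r.delta_t for r in rates_list],
            }
        )

    result = PipelineResult(
        params=params,
        fit=fit,
        rates=rates_list,
        biases=bias_list,
        audits=audit_list,
        table=table,
        report=report,
        violations=violations,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), options)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, options: RunOptions) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    table = result.table
    rate_cols = [c for c in ("date", "lg", "lgm", "lga", "lgp", "p", "delta_t") if c in table]
    table[rate_cols].to_csv(out_dir / "rates.csv", index=False)
    bias_cols = [c for c in ("date", "bm", "ba", "bp", "cap", "bap", "bmp", "blap", "bp_upper")
                 if c in table]
    table[bias_cols].to_csv(out_dir / "bias.csv", index=False)

    audit_payload = {
        "max_shoot_residual": max(a.max_shoot_residual for a in result.audits),
        "max_campaign_residual": max(a.campaign_residual for a in result.audits),
        "max_marking_residual": max(a.max_marking_residual for a in result.audits),
        "max_campaign_marking_residual": max(
            a.campaign_marking_residual for a in result.audits
        ),
        "mean_rswa": (
            None
            if any(a.rswa_mean is None for a in result.audits)
            else float(np.mean([a.rswa_mean for a in result.audits]))
        ),
        "violations": result.violations,
    }
    (out_dir / "audit.json").write_text(json.dumps(audit_payload, indent=2))

    payload: dict = {
        "params": {"alpha": result.params.alpha, "beta": result.params.beta},
        "params_source": options.params_source,
    }
    if result.fit is not None:
        payload["fit"] = {
            "alpha": result.fit.params.alpha,
            "beta": result.fit.params.beta,
            "r_squared": result.fit.r_squared,
            "r_squared_log": result.fit.r_squared_log,
            "n": result.fit.n,
        }
    if result.report is not None:
        payload["methods"] = [
            {
                "method": m.method,
                "rmse": m.rmse,
                "ccc": m.ccc,
                "ccc_ci": list(m.ccc_ci),
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "through_origin": m.through_origin,
            }
            for m in result.report.methods
        ]
        payload["bias_ordering_fraction"] = result.report.bias_ordering_fraction
        payload["n_campaigns"] = result.report.n_campaigns
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))

    if options.make_plot and "lg" in table:
        plot_rate_series(table, out_dir / "rates.png")
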