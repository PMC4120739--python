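"""End-to-end analysis workflow and run manifests.

`run_analyze` implements the recommended five-step analysis: choose a
loss, tune (d, M) by the bootstrap with the one-SE rule, screen the most
important variables for total interaction strength against the
parametric-bootstrap null, drill down into two-way and higher-order
subsets seeded by the significant lower orders, and write tables and
figures.  Every command writes a JSON run manifest with the
configuration snapshot, seeds and SHA-256 digests of all artifacts, so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .boosting import GbmParams
from .interaction import assessments_to_frame
from .model import BoostedTreeModel
from .simulate import SimulationConfig, simulate_study

__all__ = ["run_simulate", "run_analyze", "run_power", "write_manifest"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, command: str, config: dict, seed, extra=None) -> Path:
    out_dir = Path(out_dir)
    artifacts = {
        p.name: _digest(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": artifacts,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _gbm_params_from_config(config: dict) -> GbmParams:
    fields = GbmParams.__dataclass_fields__
    return GbmParams(**{k: v for k, v in config.items() if k in fields})


def run_simulate(config: dict, out_dir, seed: int | None = None) -> Path:
    """Generate the simulated panel + outcome and write CSV + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(
        n_subjects=int(config.get("n_subjects", 1000)),
        snr=float(config.get("snr", 2.0)),
        seed=int(seed if seed is not None else config.get("seed", 0)),
        s_method=config.get("s_method", "range"),
    )
    data, outcome = simulate_study(sim)
    data.to_csv(out_dir / "data.csv", index=False)
    write_manifest(
        out_dir, "simulate",
        {"n_subjects": sim.n_subjects, "snr": sim.snr, "s_method": sim.s_method},
        sim.seed,
        extra={"realized_snr": outcome.realized_snr, "sigma": outcome.sigma},
    )
    return out_dir / "data.csv"


def _drill_down(sig_vars, sig_pairs, order: int, cap: int):
    """Candidate subsets of a given order seeded by significant pairs."""
    pool = sorted({v for p in sig_pairs for v in p})
    out = []
    for sub in combinations(pool, order):
        if any(set(p) <= set(sub) for p in sig_pairs):
            out.append(sub)
        if len(out) >= cap:
            break
    return out


def run_analyze(
    data: pd.DataFrame,
    config: dict,
    out_dir,
    seed: int | None = None,
) -> dict:
    """Five-step interaction analysis of one dataset; returns a report dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    outcome_col = config.get("outcome", "y")

    model = BoostedTreeModel.from_dataframe(
        data, outcome=outcome_col,
        log_outcome=bool(config.get("log_outcome", False)),
    )
    params = _gbm_params_from_config(config)

    # step 2: tune unless explicit parameters were frozen in the config
    if config.get("tune", False):
        tuning = model.tune(
            d_values=config.get("d_values", (1, 2, 3, 4, 5, 6)),
            m_grid=config.get("m_grid", list(range(500, 3001, 500))),
            n_boot=int(config.get("n_boot", 25)),
            seed=seed,
            params=params,
        )
        (out_dir / "tuning.csv").write_text(tuning.grid.to_csv(index=False))
        params = tuning.best_params(params)

    res = model.fit(params.replace(seed=seed))
    importance = res.variable_importance()
    importance.rename_axis("variable").to_csv(out_dir / "importance.csv")

    report: dict = {
        "params": {"depth": params.depth, "n_trees": params.n_trees},
        "training_r2": res.rsquared,
        "top_variables": res.top_variables(int(config.get("top_k", 10))),
    }

    try:
        from .plots import plot_importance

        plot_importance(importance).figure.savefig(
            out_dir / "importance.png", bbox_inches="tight", dpi=120
        )
        plots_ok = True
    except Exception:
        plots_ok = False

    # step 3: with depth 1 the model is additive — nothing to assess
    if params.depth == 1:
        report["interactions"] = "no interaction evaluation performed (depth 1)"
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        write_manifest(out_dir, "analyze", config, seed)
        return report

    n_rep = int(config.get("null_rep", 250))
    h_rows = config.get("h_rows")
    cap = int(config.get("max_subsets", 15))
    top = report["top_variables"]

    totals = res.interaction_test(top, n_rep=n_rep, seed=seed, h_rows=h_rows)
    assessments_to_frame(totals).to_csv(out_dir / "h_total.csv", index=False)
    sig_vars = [a.subset[0] for a in totals if a.significant]
    report["interacting_variables"] = sig_vars

    pairs = list(combinations(sig_vars, 2))[:cap]
    all_assessments = list(totals)
    sig_pairs: list[tuple[str, ...]] = []
    if pairs:
        pair_tests = res.interaction_test(pairs, n_rep=n_rep, seed=seed + 1, h_rows=h_rows)
        assessments_to_frame(pair_tests).to_csv(out_dir / "h_pairs.csv", index=False)
        sig_pairs = [a.subset for a in pair_tests if a.significant]
        all_assessments += pair_tests
    report["significant_pairs"] = [list(p) for p in sig_pairs]

    # step 4: higher orders seeded by the significant pairs
    higher = []
    for order in (3, 4):
        cands = _drill_down(sig_vars, sig_pairs, order, cap)
        if not cands:
            break
        tests = res.interaction_test(cands, n_rep=n_rep, seed=seed + order, h_rows=h_rows)
        higher += tests
        sig_pairs += [a.subset for a in tests if a.significant]
    if higher:
        assessments_to_frame(higher).to_csv(out_dir / "h_higher.csv", index=False)
        all_assessments += higher
    report["significant_subsets"] = [
        list(a.subset) for a in all_assessments if a.significant
    ]

    if config.get("stability", False):
        targets = [a.subset for a in all_assessments if a.significant and a.order > 1]
        stab = res.split_stability(
            targets[:cap],
            n_repeats=int(config.get("stability_repeats", 10)),
            null_rep=int(config.get("stability_null_rep", 50)),
            seed=seed,
        )
        pd.DataFrame(
            [
                {"subset": " * ".join(s.subset), "detected": s.n_detected,
                 "repeats": s.n_repeats, "fraction": s.fraction}
                for s in stab
            ]
        ).to_csv(out_dir / "stability.csv", index=False)
        report["stability"] = {
            " * ".join(s.subset): str(s) for s in stab
        }

    if plots_ok:
        from .plots import plot_h_assessments

        plot_h_assessments(
            all_assessments, common_range=bool(config.get("common_axis", False))
        ).figure.savefig(out_dir / "h_assessments.png", bbox_inches="tight", dpi=120)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    write_manifest(out_dir, "analyze", config, seed)
    return report


def run_power(config: dict, out_dir, seed: int | None = None) -> pd.DataFrame:
    """Run both power methods over the configured cells; write CSV + plot."""
    from .power import PowerConfig, power_boosted, power_parametric

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))

    model_kind = config.get("model", "two_way")
    betas = config.get("betas", [0.25, 0.5, 1.0])
    ns = config.get("n_values", [250, 500, 1000])
    n_datasets = int(config.get("n_datasets", 20))
    B = int(config.get("B", 50))
    outer_B = int(config.get("outer_B", 20))
    gbm = _gbm_params_from_config(config.get("gbm", {"n_trees": 300, "depth": 3,
                                                    "shrinkage": 0.05,
                                                    "backend": "hist"}))
    n_rep_null = int(config.get("null_rep", 30))

    records = []
    for beta in betas:
        for n in ns:
            cell = PowerConfig(
                model=model_kind, n=int(n),
                beta12=float(beta), beta_two_way=float(beta),
                beta123=float(config.get("beta123", beta)),
                n_datasets=n_datasets, B=B, outer_B=outer_B, seed=seed,
            )
            records.append(power_boosted(cell, gbm, n_rep_null).to_record())
            records.append(power_parametric(cell).to_record())
    table = pd.DataFrame(records)
    table.to_csv(out_dir / "power.csv", index=False)

    try:
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for (method, beta), sub in table.groupby(["method", "beta12"]):
            ax.plot(sub["n"], sub["power"], marker="o",
                    label=f"{method}, beta={beta}")
        ax.set_xlabel("sample size")
        ax.set_ylabel("power")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7)
        fig.savefig(out_dir / "power.png", bbox_inches="tight", dpi=120)
    except Exception:
        pass

    write_manifest(
        out_dir, "power", config, seed,
        extra={"budgets": {"n_datasets": n_datasets, "B": B, "outer_B": outer_B}},
    )
    return table
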