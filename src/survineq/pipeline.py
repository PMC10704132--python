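"""End-to-end orchestration: reconstruct → pool → fit → select → inequality → PSA.

The run configuration (YAML/JSON mapping or plain dict) lists, per study,
the coordinate/risk/meta files for both arms, the selection gates, the
stratifications, the number of probabilistic draws, and a root seed. All
stage randomness (mixture multi-starts, parameter draws) flows from that
root seed, and every output file embeds provenance (input hashes, config
echo, seed, package version) so a repeated run is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .exceptions import InputError
from .families import canonical_name, get_family, MixtureFamily
from .inequality import (
    health_distribution,
    inequality_impact,
    inequality_summary,
)
from .io import file_sha256, read_curve, write_ipd, write_json
from .model_selection import SelectionConfig, select_family
from .pooling import pool_arms
from .probabilistic import probabilistic_inequality
from .pseudo_ipd import reconstruct_ipd, validate_reconstruction
from .survival_models import fit_mixture, fit_parametric, parameter_covariance

__all__ = ["run_pipeline", "materialize_archetype"]

logger = logging.getLogger(__name__)

ARMS = ("intervention", "comparator")


def _stage_seed(root_seed: int, stage: str, *extra) -> int:
    import zlib

    ss = np.random.SeedSequence(
        [int(root_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
        + [zlib.crc32(str(e).encode()) for e in extra]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _selection_config(payload: dict) -> SelectionConfig:
    return SelectionConfig(
        seer_rate=float(payload["seer_rate"]),
        uplift=float(payload.get("uplift", 0.10)),
        horizon=float(payload.get("horizon_months", 120.0)),
        groups=tuple(payload.get("groups", (2, 5))),
        require_evaluable_quantiles=bool(
            payload.get("require_evaluable_quantiles", True)
        ),
        veto=tuple(payload.get("veto", ())),
    )


def _fit_candidate(family: str, ipd, seed: int, n_starts: int):
    family = canonical_name(family)
    if isinstance(get_family(family), MixtureFamily):
        return fit_mixture(ipd, family, n_starts=n_starts, seed=seed)
    return fit_parametric(ipd, family)


def _summary_table(result, groups) -> str:
    """Human-readable table mirroring the per-metric layout of the results."""
    lines = []
    header = f"{'metric':<12}{'intervention':>22}{'comparator':>22}{'difference':>22}{'relative':>28}"
    lines.append(header)
    lines.append("-" * len(header))

    def cell(stats):
        return f"{stats['mean']:.1f} ({stats['lower']:.1f}; {stats['upper']:.1f})"

    for metric in [f"{g}-group" for g in groups] + (["IG"] if 5 in groups else []):
        stats = result["probabilistic"]["metrics"][metric]
        rel = stats["relative_change"]
        rel_cell = f"{rel['mean']:.1f}% ({rel['lower']:.1f}%; {rel['upper']:.1f}%)"
        lines.append(
            f"{metric:<12}"
            f"{cell(stats['intervention']):>22}"
            f"{cell(stats['comparator']):>22}"
            f"{cell(stats['absolute_change']):>22}"
            f"{rel_cell:>28}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full analysis described by a configuration mapping.

    Writes reconstructed IPD, per-family fits, the selection audit, and the
    results bundle under ``out_dir``; returns the results dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    draws = int(config.get("draws", 1000))
    groups = tuple(sorted(int(g) for g in config.get("groups", (2, 5))))
    if any(g < 2 or g > 10 for g in groups):
        raise InputError("stratifications must lie in 2..10")
    sel_payload = dict(config["selection"])
    sel_payload.setdefault("groups", groups)
    sel_config = _selection_config(sel_payload)
    candidates = [canonical_name(c) for c in sel_payload.get("candidates") or []]
    if not candidates:
        from .model_selection import default_candidates

        candidates = list(default_candidates())
    n_starts = int(config.get("mixture_starts", 10))

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "input_hashes": {},
    }

    # stage 1: reconstruction
    per_arm: dict[str, list] = {arm: [] for arm in ARMS}
    validations = {}
    for study_entry in config["studies"]:
        study = study_entry["study"]
        for arm in ARMS:
            files = study_entry["arms"][arm]
            curve = read_curve(files["coords"], files.get("risk"), files.get("meta"))
            for key in ("coords", "risk", "meta"):
                if files.get(key):
                    provenance["input_hashes"][str(files[key])] = file_sha256(files[key])
            ipd = reconstruct_ipd(curve)
            report = validate_reconstruction(
                ipd, curve, published_events=curve.total_events
            )
            logger.info(
                "reconstructed %s/%s: n=%d events=%d max|ΔKM|=%.4f",
                study, arm, ipd.n, report.events_reconstructed,
                report.max_abs_deviation,
            )
            write_ipd(ipd, out_dir / f"ipd_{study}_{arm}.csv")
            validations[f"{study}/{arm}"] = report.to_dict()
            per_arm[arm].append(ipd)

    # stage 2: pooling
    pooled = {arm: pool_arms(per_arm[arm]) for arm in ARMS}
    for arm in ARMS:
        write_ipd(pooled[arm], out_dir / f"pooled_{arm}.csv")
        logger.info(
            "pooled %s: %d records, total weight %.1f, weighted events %.1f",
            arm, pooled[arm].n, pooled[arm].total_weight, pooled[arm].n_events,
        )

    # stage 3: candidate fits
    fits = {arm: {} for arm in ARMS}
    for arm in ARMS:
        for family in candidates:
            fit = _fit_candidate(
                family, pooled[arm], _stage_seed(seed, "fit", arm, family), n_starts
            )
            fits[arm][family] = fit
            logger.info("fit %s/%s: loglik=%.2f AIC=%.2f", arm, family,
                        fit.loglik, fit.aic)

    # stage 4: selection
    selection = select_family(fits["intervention"], fits["comparator"], sel_config)
    logger.info("selected family: %s", selection.selected)
    write_json(selection.to_dict(), out_dir / "selection.json")

    chosen = {arm: fits[arm][selection.selected] for arm in ARMS}
    for arm in ARMS:
        parameter_covariance(chosen[arm], pooled[arm])
        write_json(
            {**chosen[arm].to_dict(), "provenance": {"arm": arm, "seed": seed}},
            out_dir / f"model_{arm}.json",
        )

    # stage 5: deterministic inequality at the MLE
    deterministic = {}
    for arm in ARMS:
        deterministic[arm] = {}
        for g in groups:
            hd = health_distribution(chosen[arm], g)
            deterministic[arm][f"{g}-group"] = {
                "health_distribution": hd.to_dict(),
                "summary": inequality_summary(hd).to_dict(),
            }
    impacts = {}
    for g in groups:
        s_int = inequality_summary(health_distribution(chosen["intervention"], g))
        s_comp = inequality_summary(health_distribution(chosen["comparator"], g))
        for metric, impact in inequality_impact(s_int, s_comp).items():
            impacts[metric] = impact.to_dict()

    # stage 6: probabilistic analysis
    psa = probabilistic_inequality(
        chosen["intervention"],
        chosen["comparator"],
        groups=groups,
        n=draws,
        seed=_stage_seed(seed, "psa"),
    )

    results = {
        "provenance": provenance,
        "validation": validations,
        "selection": selection.to_dict(),
        "deterministic": {"per_arm": deterministic, "impacts": impacts},
        "probabilistic": psa.to_dict(),
    }
    write_json(results, out_dir / "results.json")
    (out_dir / "summary.txt").write_text(_summary_table(results, groups))
    return results


def materialize_archetype(name: str, input_dir, seed: int, draws: int = 1000) -> dict:
    """Simulate and digitize one bundled archetype; return its run config.

    Writes the coordinate, risk-table and metadata files the pipeline reads
    under ``input_dir`` — the synthetic stand-in for a set of digitized
    trial publications.
    """
    from .fixtures import ARCHETYPES, archetype_run_config, truth_specs
    from .io import write_curve
    from .synthetic import digitize, simulate_trial

    archetype = ARCHETYPES[name]
    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    for arm, specs in truth_specs(archetype, seed).items():
        for spec in specs:
            ipd = simulate_trial(spec)
            curve = digitize(ipd, risk_interval=archetype.risk_interval)
            stem = f"{spec.study_label}_{arm}"
            write_curve(
                curve,
                input_dir / f"{stem}_coords.csv",
                input_dir / f"{stem}_risk.csv",
                input_dir / f"{stem}_meta.yaml",
            )
    return archetype_run_config(archetype, input_dir, seed, draws=draws)
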