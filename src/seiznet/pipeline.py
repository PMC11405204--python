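"""End-to-end orchestration of the MEA and icEEG analysis paths.

``run_mea_pipeline`` realizes the day-by-day experiment: simulate (or
load) per-well per-day spike trains, bin them, detect and exclude
population bursts, compute pairwise Fisher-z FC, embed each well's FC
trajectory, and compare treated vs control groups (normalized MFR per
day, strong-edge counts and trajectory distance on the final day),
Holm-corrected. Every stage writes its artifact so each step is
independently inspectable, and a manifest records every parameter that
affects the output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snio
from ._seeds import child_seed
from .connectivity import bin_spike_counts, pairwise_fc, threshold_network
from .embedding import compare_group_distances, embed_well
from .iceeg import compare_soz_pairs, compute_plc_table
from .spikes import detect_population_bursts, mean_firing_rate, normalize_mfr
from .stats import holm_bonferroni, two_sample_t
from .synth import TreatmentDesign, WellConfig, simulate_iceeg_cohort, simulate_treatment_course

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_mea_pipeline", "run_iceeg_pipeline"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every field lands in the manifest."""

    outdir: str = "seiznet_run"
    seed: int = 0
    scenario: str | None = None  # YAML path; None = defaults below
    bin_width: float = 0.05
    burst_frac_active: float = 0.25
    burst_rate_sd: float = 3.0
    exclude_bursts: bool = True
    z_min: float = 0.80
    coupling_fraction: float = 0.05  # used when no scenario is given
    coupling_weight: float = 0.3
    log_level: str = "INFO"
    # icEEG path
    iceeg_n_patients: int = 3
    iceeg_band: tuple = (70.0, 90.0)
    iceeg_kappa_sp: float = 2.0
    iceeg_kappa_control: float = 0.5
    write_spikes: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if "iceeg_band" in d:
            cfg.iceeg_band = tuple(d["iceeg_band"])
        return cfg


def _manifest(config: RunConfig, extra: dict) -> dict:
    import scipy

    from . import __version__

    man = {
        "seiznet_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config": dataclasses.asdict(config),
    }
    man.update(extra)
    return man


def run_mea_pipeline(config: RunConfig) -> dict:
    """Simulate and analyze a full multi-well treatment experiment.

    Returns the run manifest (also written to ``manifest.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.scenario:
        well, design, extra = snio.load_scenario(config.scenario)
    else:
        from .synth import default_treatment_scenario

        well, design, extra = default_treatment_scenario(
            seed=config.seed,
            background_fraction=config.coupling_fraction,
            background_weight=config.coupling_weight,
        )

    recordings = simulate_treatment_course(well, design, seed=config.seed)
    counts = {"recordings": len(recordings)}

    mfr_rows, fc_by_well, edge_rows = [], {}, []
    for rec in recordings:
        tag = f"well{rec.well_id:02d}_day{rec.day}"
        try:
            if config.write_spikes:
                snio.write_spike_csv(rec.trains, out / f"spikes_{tag}.csv")
            binned = bin_spike_counts(rec.trains, config.bin_width)
            binned.burst_mask = detect_population_bursts(
                binned, config.burst_frac_active, config.burst_rate_sd
            )
            fc = pairwise_fc(binned, exclude_bursts=config.exclude_bursts)
            snio.write_fc_long_csv(fc, out / f"fc_{tag}.csv")
            net = threshold_network(fc, config.z_min)
            mfr = mean_firing_rate(rec.trains)
            mfr_rows.append(
                {
                    "well": rec.well_id,
                    "group": rec.group,
                    "day": rec.day,
                    "well_mean_hz": mfr.well_mean_hz,
                    "n_burst_bins": int(binned.burst_mask.bin_flags.sum()),
                    "n_bins_used": fc.n_bins_used,
                    "mean_z": fc.mean_z(),
                    "n_strong_edges": net.n_edges,
                }
            )
            edge_rows.append((rec.well_id, rec.group, rec.day, net.n_edges))
            fc_by_well.setdefault((rec.well_id, rec.group), []).append((rec.day, fc))
        except Exception as exc:
            raise RuntimeError(
                f"MEA pipeline failed at well {rec.well_id}, day {rec.day}: {exc}"
            ) from exc
    summary = pd.DataFrame(mfr_rows)
    # normalized MFR relative to each well's Day-0 recording
    base = summary[summary.day == 0].set_index("well")["well_mean_hz"]
    summary["mfr_ratio"] = summary.apply(
        lambda r: r.well_mean_hz / base[r.well] if base[r.well] > 0 else np.nan,
        axis=1,
    )
    summary.to_csv(out / "well_summary.csv", index=False)

    traj_rows = []
    distances = {}
    for (well_id, group), day_fcs in sorted(fc_by_well.items()):
        day_fcs.sort(key=lambda t: t[0])
        try:
            traj = embed_well([fc for _, fc in day_fcs])
        except Exception as exc:
            raise RuntimeError(
                f"embedding failed for well {well_id}: {exc}"
            ) from exc
        distances[(well_id, group)] = traj.distances
        for d, (day, _) in enumerate(day_fcs):
            traj_rows.append(
                {
                    "well": well_id,
                    "group": group,
                    "day": day,
                    "pc1": traj.pc_coords[d, 0],
                    "pc2": traj.pc_coords[d, 1],
                    "dist_to_day0": traj.distances[d],
                }
            )
    traj_df = pd.DataFrame(traj_rows)
    traj_df.to_csv(out / "trajectories.csv", index=False)

    # group comparisons
    stats_rows = []
    last_day = design.n_days - 1
    for day in range(1, design.n_days):
        tr = summary[(summary.group == "treated") & (summary.day == day)]["mfr_ratio"]
        co = summary[(summary.group == "control") & (summary.day == day)]["mfr_ratio"]
        res = two_sample_t(tr.to_numpy(), co.to_numpy())
        stats_rows.append(("mfr_ratio_day%d" % day, res))
    tr_e = summary[(summary.group == "treated") & (summary.day == last_day)][
        "n_strong_edges"
    ].to_numpy(float)
    co_e = summary[(summary.group == "control") & (summary.day == last_day)][
        "n_strong_edges"
    ].to_numpy(float)
    stats_rows.append(("strong_edges_day%d" % last_day, two_sample_t(tr_e, co_e)))
    tr_d = np.array(
        [d[last_day] for (w, g), d in distances.items() if g == "treated"]
    )
    co_d = np.array(
        [d[last_day] for (w, g), d in distances.items() if g == "control"]
    )
    stats_rows.append(
        ("distance_day%d" % last_day, compare_group_distances(tr_d, co_d))
    )
    stats_df = pd.DataFrame(
        [
            {
                "comparison": name,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "d": r.cohen_d,
                "ci_lo": r.ci_low,
                "ci_hi": r.ci_high,
                "test_kind": r.kind,
            }
            for name, r in stats_rows
        ]
    )
    reject, p_adj = holm_bonferroni(stats_df["p"].to_numpy())
    stats_df["p_holm"] = p_adj
    stats_df["reject_holm"] = reject
    stats_df.to_csv(out / "stats.csv", index=False)

    counts.update(
        {
            "wells": design.n_treated_wells + design.n_control_wells,
            "days": design.n_days,
            "fc_files": len(recordings),
            "trajectories": len(distances),
            "comparisons": len(stats_df),
        }
    )
    man = _manifest(config, {"stage_counts": counts, "kind": "mea"})
    (out / "manifest.json").write_text(json.dumps(man, indent=1, default=str))
    return man


def run_iceeg_pipeline(config: RunConfig, signals=None) -> dict:
    """Phase-locking analysis path: PLC table, class means, paired test.

    ``signals`` may supply pre-loaded :class:`ContactSignal` epochs
    (e.g. from files); by default a synthetic cohort is generated from
    the run seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if signals is None:
        signals = simulate_iceeg_cohort(
            n_patients=config.iceeg_n_patients,
            band=tuple(config.iceeg_band),
            kappa_sp=config.iceeg_kappa_sp,
            kappa_control=config.iceeg_kappa_control,
            seed=child_seed(config.seed, 0xEE),
        )
    missing = [s.contact for s in signals if s.region_class not in ("SOZ", "SP", "control")]
    if missing:
        raise ValueError(f"unlabeled contacts: {missing}")
    plc = compute_plc_table(signals, band=tuple(config.iceeg_band))
    plc.to_csv(out / "plc_pairs.csv", index=False)
    res, means = compare_soz_pairs(plc)
    means.to_csv(out / "plc_patient_means.csv")
    stats_df = pd.DataFrame(
        [
            {
                "comparison": "soz_sp_vs_soz_control",
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "d": res.cohen_d,
                "ci_lo": res.ci_low,
                "ci_hi": res.ci_high,
                "test_kind": res.kind,
            }
        ]
    )
    stats_df.to_csv(out / "plc_stats.csv", index=False)
    man = _manifest(
        config,
        {
            "stage_counts": {
                "contacts": len({(s.patient, s.contact) for s in signals}),
                "pair_rows": len(plc),
                "patients_tested": len(means),
            },
            "kind": "iceeg",
        },
    )
    (out / "manifest_iceeg.json").write_text(json.dumps(man, indent=1, default=str))
    return man
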