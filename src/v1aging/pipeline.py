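"""End-to-end orchestration: simulate -> analyze -> compare -> report.

``run_pipeline`` drives the full study on synthetic data: it simulates a
young and an old population of tuned spiking neurons, runs the per-neuron
analysis chain, assembles the group comparisons (summaries, binned
distributions with chi-square, t-tests, percent changes), quantifies
synthetic double-label histology with the age x layer ANOVA, compares
fluorescence-intensity and blot summaries, and reproduces the
percent-change block implied by the published group means.  Everything is
deterministic given (config, seed); exclusions are logged, never silent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .groupstats import (
    DEFAULT_BIN_SPECS,
    bin_distribution,
    chi_square_test,
    percent_change,
    summarize_group,
    t_test,
    two_way_anova,
)
from .histology import aoi_counts_from_map, blot_od_ratio, layer_density_table
from .spikes import SpikeTrain, StimulusProtocol, Trial, TrialSet
from .synthetic import (
    BlotGroupSpec,
    CellMapSpec,
    GroupPreset,
    make_blot_lanes,
    make_cell_map,
    make_population,
    matched_truncnorm_at_zero,
    old_preset,
    simulate_trials,
    young_preset,
)
from .tuning import analyze_neuron

RESPONSE_METRICS = ("osi", "dsi", "or", "ar", "sa", "snr")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    n_young: int | None = None  # None -> published sample sizes
    n_old: int | None = None
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    aoi_area_mm2: float = 0.05
    n_aois_per_layer: int = 61
    n_intensity_slices: int = 60
    n_blot_lanes: int = 6

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    config: RunConfig
    config_hash: str
    neurons: pd.DataFrame
    group_summaries: pd.DataFrame
    distributions: pd.DataFrame
    tests: pd.DataFrame
    percent_changes_simulated: pd.DataFrame
    reproduction: dict
    density_summary: pd.DataFrame
    density_anova: pd.DataFrame
    marker_comparisons: pd.DataFrame
    exclusions: pd.DataFrame


def analyze_population(
    preset: GroupPreset, protocol: StimulusProtocol, seed: int
) -> pd.DataFrame:
    """Simulate and analyze one group; one row per neuron with truth columns."""
    rng = np.random.default_rng(seed)
    population = make_population(preset, seed=int(rng.integers(2**31)))
    rows = []
    for i, gt in enumerate(population):
        nid = f"{preset.name}-{i:03d}"
        trial_set = simulate_trials(
            gt, protocol, seed=int(rng.integers(2**31)), neuron_id=nid
        )
        rec = analyze_neuron(trial_set, depth_um=gt.depth_um)
        rows.append(
            {
                "neuron_id": nid,
                "group": preset.name,
                "osi": rec.osi,
                "dsi": rec.dsi,
                "or": rec.or_,
                "ar": rec.ar,
                "sa": rec.sa,
                "snr": rec.snr,
                "cell_class": rec.cell_class,
                "modulation": rec.modulation,
                "depth_um": rec.depth_um,
                "layer": rec.layer,
                "fit_mse": rec.fit.mse if rec.fit else np.nan,
                "fit_accepted": bool(rec.fit.accepted) if rec.fit else False,
                "flags": ";".join(rec.flags),
                "osi_true": gt.osi_true,
                "dsi_true": gt.dsi_true,
                "or_true": gt.or_true,
                "sa_true": gt.sa_true,
                "simple_true": gt.is_simple_true,
            }
        )
    return pd.DataFrame(rows)


def population_comparison(neurons: pd.DataFrame) -> tuple[pd.DataFrame, ...]:
    summaries, dist_rows, test_rows, change_rows = [], [], [], []
    young = neurons[neurons["group"] == "young"]
    old = neurons[neurons["group"] == "old"]
    for metric in RESPONSE_METRICS:
        counts = {}
        for gname, gdf in (("young", young), ("old", old)):
            vals = gdf[metric].dropna().to_numpy(dtype=float)
            s = summarize_group(vals, group=gname, metric=metric)
            summaries.append(
                {"metric": metric, "group": gname, "mean": s.mean, "sd": s.sd, "n": s.n}
            )
            spec = DEFAULT_BIN_SPECS[metric]
            c, pct = bin_distribution(vals, spec)
            counts[gname] = c
            for b, ci, pi in zip(spec.bins, c, pct):
                dist_rows.append(
                    {
                        "metric": metric,
                        "group": gname,
                        "bin": b.label,
                        "count": int(ci),
                        "percent": float(pi),
                    }
                )
        stat, dof, p = chi_square_test(np.vstack([counts["young"], counts["old"]]))
        test_rows.append(
            {"metric": metric, "test": "chi2_bins", "statistic": stat, "df": dof, "p": p}
        )
        t, tdf, p2 = t_test(
            young[metric].dropna(), old[metric].dropna(), tails=2, variant="welch"
        )
        test_rows.append(
            {"metric": metric, "test": "welch_t_two_tailed", "statistic": t,
             "df": tdf, "p": p2}
        )
        ym = float(young[metric].dropna().mean())
        om = float(old[metric].dropna().mean())
        decimals = 0 if metric == "sa" else 1
        change_rows.append(
            {"metric": metric, "young_mean": ym, "old_mean": om,
             "percent_change": percent_change(ym, om, decimals=decimals)}
        )
    # layer distribution and simple/complex comparisons
    layer_tab = (
        neurons.groupby(["group", "layer"], sort=True).size().unstack(fill_value=0)
    )
    stat, dof, p = chi_square_test(layer_tab.to_numpy())
    test_rows.append(
        {"metric": "layer_distribution", "test": "chi2", "statistic": stat,
         "df": dof, "p": p}
    )
    cls = neurons.dropna(subset=["cell_class"])
    cls_tab = (
        cls.groupby(["group", "cell_class"], sort=True).size().unstack(fill_value=0)
    )
    if cls_tab.shape == (2, 2) and (cls_tab.to_numpy() > 0).all():
        stat, dof, p = chi_square_test(cls_tab.to_numpy())
        test_rows.append(
            {"metric": "simple_complex", "test": "chi2", "statistic": stat,
             "df": dof, "p": p}
        )
    return (
        pd.DataFrame(summaries),
        pd.DataFrame(dist_rows),
        pd.DataFrame(test_rows),
        pd.DataFrame(change_rows),
    )


def reproduce_reported_changes() -> dict:
    """Percent-change block and layer-wise ratio decreases from the
    published group means — the reproduction of the printed summary
    numbers from their printed inputs."""
    g = reference.GROUP_STATS
    changes = {
        "or": percent_change(g["or"]["young"][0], g["or"]["old"][0], decimals=1),
        "ar": percent_change(g["ar"]["young"][0], g["ar"]["old"][0], decimals=1),
        "sa": percent_change(g["sa"]["young"][0], g["sa"]["old"][0], decimals=0),
        "snr": percent_change(g["snr"]["young"][0], g["snr"]["old"][0], decimals=1),
    }
    layer_decreases = {
        layer: -percent_change(
            reference.GABA_PROPORTION["young"][layer][0],
            reference.GABA_PROPORTION["old"][layer][0],
            decimals=1,
        )
        for layer in reference.CORTICAL_LAYERS
    }
    return {"percent_changes": changes, "gaba_ratio_decreases": layer_decreases}


def histology_comparison(
    config: RunConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    frames = []
    for group in ("young", "old"):
        for layer in reference.CORTICAL_LAYERS:
            spec = CellMapSpec(
                layer=layer,
                neun_density=reference.NEUN_DENSITY[group][layer][0],
                gaba_fraction=reference.GABA_PROPORTION[group][layer][0] / 100.0,
                aoi_area_mm2=config.aoi_area_mm2,
                n_aois=config.n_aois_per_layer,
            )
            cmap = make_cell_map(spec, seed=int(rng.integers(2**31)))
            df = aoi_counts_from_map(cmap.aois)
            df.insert(0, "group", group)
            frames.append(df)
    per_aoi = pd.concat(frames, ignore_index=True)
    summary, long = layer_density_table(per_aoi)
    anova_rows = []
    for value_col in ("neun_density", "gaba_density", "proportion_pct"):
        effects = two_way_anova(long[value_col], long["group"], long["layer"])
        F, df1, df2, p = effects["age"]
        anova_rows.append(
            {"measure": value_col, "effect": "age", "F": F, "df1": df1,
             "df2": df2, "p": p}
        )
    return summary, pd.DataFrame(anova_rows)


def marker_comparison(config: RunConfig, seed: int) -> pd.DataFrame:
    """Fluorescence-intensity and blot comparisons for the three markers."""
    rng = np.random.default_rng(seed)
    rows = []
    for marker in ("gad65", "gad67", "gabaa_r_alpha1"):
        samples = {}
        for group in ("young", "old"):
            mean, sd = reference.FLUOR_INTENSITY[marker][group]
            dist = matched_truncnorm_at_zero(mean, sd)
            samples[group] = dist.rvs(config.n_intensity_slices, random_state=rng)
        t, df, p2 = t_test(samples["young"], samples["old"], tails=2)
        _, _, p1 = t_test(samples["young"], samples["old"], tails=1)
        rows.append(
            {"marker": marker, "assay": "fluorescence",
             "young_mean": float(np.mean(samples["young"])),
             "old_mean": float(np.mean(samples["old"])),
             "t": t, "df": df, "p_two_tailed": p2, "p_one_tailed": p1}
        )
        ratios = {}
        for group in ("young", "old"):
            mean, sd = reference.BLOT_RATIO[marker][group]
            lanes = make_blot_lanes(
                BlotGroupSpec(group, marker, target_mean=mean, target_sd=sd),
                n_per_group=config.n_blot_lanes,
                seed=int(rng.integers(2**31)),
            )
            ratios[group] = [blot_od_ratio(lane) for lane in lanes]
        t, df, p2 = t_test(ratios["young"], ratios["old"], tails=2)
        _, _, p1 = t_test(ratios["young"], ratios["old"], tails=1)
        rows.append(
            {"marker": marker, "assay": "blot",
             "young_mean": float(np.mean(ratios["young"])),
             "old_mean": float(np.mean(ratios["old"])),
             "t": t, "df": df, "p_two_tailed": p2, "p_one_tailed": p1}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> StudyReport:
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    young = analyze_population(
        young_preset(config.n_young), config.protocol, seeds[0]
    )
    old = analyze_population(old_preset(config.n_old), config.protocol, seeds[1])
    neurons = pd.concat([young, old], ignore_index=True)

    summaries, distributions, tests, changes = population_comparison(neurons)
    density_summary, density_anova = histology_comparison(config, seeds[2])
    markers = marker_comparison(config, seeds[3])

    exclusions = neurons.loc[neurons["flags"] != "",
                             ["neuron_id", "group", "flags"]].reset_index(drop=True)

    return StudyReport(
        config=config,
        config_hash=config.hash(),
        neurons=neurons,
        group_summaries=summaries,
        distributions=distributions,
        tests=tests,
        percent_changes_simulated=changes,
        reproduction=reproduce_reported_changes(),
        density_summary=density_summary,
        density_anova=density_anova,
        marker_comparisons=markers,
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ["neuron_id", "direction_deg", "rep", "epoch", "spike_time_s"]


def write_trials(trial_sets: list[TrialSet], path: str | Path) -> None:
    """Serialize trial sets to long CSV (one row per spike) plus a JSON
    sidecar carrying the protocol and the trial grid (so empty trials and
    spike-free neurons survive a round trip)."""
    path = Path(path)
    rows = []
    neuron_ids = []
    protocol = None
    for ts in trial_sets:
        neuron_ids.append(ts.neuron_id)
        protocol = ts.protocol
        for tr in ts.trials:
            for epoch, train in (("prestim", tr.prestim), ("stim", tr.stim)):
                for t in train.times_s:
                    rows.append(
                        {
                            "neuron_id": ts.neuron_id,
                            "direction_deg": tr.direction_deg,
                            "rep": tr.rep,
                            "epoch": epoch,
                            "spike_time_s": float(t),
                        }
                    )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)
    sidecar = {
        "neuron_ids": neuron_ids,
        "protocol": asdict(protocol) if protocol else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trials(path: str | Path) -> list[TrialSet]:
    """Inverse of :func:`write_trials`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    proto_dict = sidecar["protocol"]
    proto_dict["directions_deg"] = tuple(proto_dict["directions_deg"])
    protocol = StimulusProtocol(**proto_dict)
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing required column(s): {sorted(missing)}")
    out = []
    grouped = {k: g for k, g in df.groupby("neuron_id")} if len(df) else {}
    for nid in sidecar["neuron_ids"]:
        g = grouped.get(nid)
        trials = []
        for direction in protocol.directions_deg:
            for rep in range(protocol.n_reps):
                trains = {}
                for epoch, dur in (
                    ("prestim", protocol.prestim_duration_s),
                    ("stim", protocol.stim_duration_s),
                ):
                    if g is not None:
                        sel = g[
                            (g["direction_deg"] == direction)
                            & (g["rep"] == rep)
                            & (g["epoch"] == epoch)
                        ]
                        times = np.sort(sel["spike_time_s"].to_numpy(dtype=float))
                    else:
                        times = np.empty(0)
                    trains[epoch] = SpikeTrain(times, epoch, dur)
                trials.append(
                    Trial(
                        direction_deg=float(direction),
                        rep=rep,
                        stim=trains["stim"],
                        prestim=trains["prestim"],
                    )
                )
        out.append(TrialSet(neuron_id=nid, protocol=protocol, trials=trials))
    return out


def write_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write the study report as CSV/JSON files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "neurons": report.neurons,
        "group_summaries": report.group_summaries,
        "distributions": report.distributions,
        "tests": report.tests,
        "percent_changes_simulated": report.percent_changes_simulated,
        "density_summary": report.density_summary,
        "density_anova": report.density_anova,
        "marker_comparisons": report.marker_comparisons,
        "exclusions": report.exclusions,
    }
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    summary = {
        "seed": report.config.seed,
        "config_hash": report.config_hash,
        "reproduction": report.reproduction,
    }
    p = outdir / "report.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    paths["report"] = p
    return paths
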