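"""Orchestration: tie detection, graph and network statistics into runs.

`run_pipeline` drives the file-based workflow (mask + traces in, tables
out); the experiment helpers (`concentration_series`, `encoding_experiment`,
`within_between_correlation`) run fully synthetic end-to-end studies used by
the examples and the acceptance script.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .centrality import centrality_table
from .communities import (
    community_metrics,
    find_communities,
    permutation_null,
    select_top_responders,
)
from .config import AGONISTS, RunConfig, SimulationConfig, save_config
from .dose import classify_encoding, fit_curve, overlap_analysis
from .events import TraceSet, detect_all_events, summarize_cells
from .graph import build_tissue_graph, graph_stats
from .influence import (
    build_cases,
    characteristics_by_k,
    compute_window,
    probability_by_k,
    temporal_permutation,
)
from .simulate import simulate_dataset, simulate_traces
from .xcorr import align_and_window, connectivity_summary, correlation_matrix

logger = logging.getLogger("vasonet")

STAGES = ("detect", "graph", "communities", "centrality", "influence", "xcorr")


def read_inputs(config: RunConfig):
    """Load and cross-validate the label mask and trace table."""
    if config.mask_path is None or config.traces_path is None:
        raise ValueError("mask_path and traces_path must be set")
    mask = vio.read_mask(config.mask_path)
    traces = vio.read_traces(config.traces_path, stimulus_onset=config.stimulus_onset)
    labels = {int(l) for l in np.unique(mask) if l > 0}
    extra = [c for c in traces.cell_ids if c not in labels]
    if extra:
        raise ValueError(f"trace columns without a mask label: {extra}")
    return mask, traces


def analyze_dataset(
    traces: TraceSet,
    tg,
    config: RunConfig | None = None,
    agonist: str = "ACh",
) -> dict:
    """Detection through permutation statistics for one recording.

    Returns a bundle with the event table, per-cell summaries, responder set,
    community partition/metrics and their activity-randomization null.
    """
    cfg = config or RunConfig()
    events = detect_all_events(
        traces,
        threshold_mult=cfg.threshold_mult,
        baseline_span=cfg.baseline_span,
        window=cfg.savgol_window,
        order=cfg.savgol_order,
        merge_gap=cfg.merge_gap,
        split_frac=cfg.split_frac,
    )
    onset = traces.stimulus_onset if traces.stimulus_onset is not None else 0.0
    exposure = (onset, float(traces.time[-1]))
    summaries = summarize_cells(events, traces.cell_ids, exposure)
    responders = select_top_responders(summaries, tg, cfg.responder_fraction, agonist)
    partition = find_communities(tg, responders)
    metrics = community_metrics(tg, partition)
    null = permutation_null(
        tg, len(responders.cells), n_perm=cfg.n_perm, seed=cfg.rng_seed, observed=metrics
    )
    return {
        "agonist": agonist,
        "events": events,
        "summaries": summaries,
        "responders": responders,
        "partition": partition,
        "metrics": metrics,
        "null": null,
    }


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """File-based run: reads inputs, executes the requested stages, writes tables.

    Every output directory carries the config snapshot so a run can be
    reproduced exactly; all randomized stages derive their seeds from
    ``config.rng_seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "run_config.yaml")
    mask, traces = read_inputs(config)
    results: dict = {}

    tg = build_tissue_graph(mask, alpha=config.alpha, contact_min=config.contact_min)
    results["tissue"] = tg
    if "graph" in stages:
        edges = pd.DataFrame(sorted(tg.graph.edges()), columns=["cell_a", "cell_b"])
        edges.to_csv(out / "edges.csv", index=False)
        tg.geometry.assign(boundary=[c in tg.boundary for c in tg.geometry.index]).to_csv(
            out / "geometry.csv", index=False
        )
        stats = graph_stats(tg)
        (out / "graph_stats.json").write_text(json.dumps(stats, indent=1))
        results["graph_stats"] = stats
        logger.info("graph: %d cells, %d interior", tg.graph.number_of_nodes(), stats["n_interior"])

    needs_detect = {"detect", "communities", "centrality", "influence", "xcorr"} & set(stages)
    if needs_detect:
        bundle = analyze_dataset(traces, tg, config, agonist=config.agonist)
        results.update(bundle)
        if "detect" in stages:
            bundle["events"].to_csv(out / "events.csv", index=False)
            bundle["summaries"].to_csv(out / "cell_summaries.csv", index=False)
            logger.info("detect: %d events", len(bundle["events"]))

    if "communities" in stages:
        part = results["partition"]
        payload = {
            "agonist": config.agonist,
            "responders": results["responders"].cells,
            "communities": [sorted(c) for c in part.communities],
            "isolated": sorted(part.isolated),
            "metrics": results["metrics"].as_dict(),
            "null": {
                m: {
                    "mean": n.null_mean,
                    "sd": n.null_sd,
                    "percentile": n.percentile,
                    "observed": n.observed,
                }
                for m, n in results["null"].items()
            },
        }
        (out / "communities.json").write_text(json.dumps(payload, indent=1))

    if "centrality" in stages:
        table = centrality_table(tg)
        table.to_csv(out / "centrality.csv")
        results["centrality"] = table

    if "influence" in stages:
        events = results["events"]
        fitted = events[events.fit_ok]
        if len(fitted):
            t_w = compute_window(events, config.window_mult)
            cases = build_cases(events, tg, t_w, results["partition"])
            curve = probability_by_k(cases)
            null = temporal_permutation(
                events, tg, t_w, results["partition"],
                n_perm=config.n_perm, seed=config.rng_seed,
            )
            curve.table.to_csv(out / "influence_curve.csv")
            chars = characteristics_by_k(cases, events)
            chars.to_csv(out / "influence_characteristics.csv")
            results["influence"] = {"t_w": t_w, "curve": curve, "null": null, "cases": cases}
            (out / "influence_null.json").write_text(
                json.dumps(
                    {
                        m: {"mean": n.null_mean, "sd": n.null_sd, "observed": n.observed,
                            "percentile": n.percentile}
                        for m, n in null.items()
                    },
                    indent=1,
                )
            )
        else:
            logger.warning("influence: no fitted events, stage skipped")

    if "xcorr" in stages:
        events = results["events"]
        fitted = events[events.fit_ok]
        if len(fitted):
            max_lag_s = compute_window(events, config.window_mult)
            (seg,) = align_and_window([traces], events=[events])
            cols = [traces.cell_ids.index(c) for c in results["responders"].cells]
            mat = correlation_matrix(
                seg[:, cols], None, int(round(max_lag_s * traces.frame_rate)),
                results["responders"].cells,
            )
            mat.to_csv(out / "xcorr_matrix.csv")
            connectivity_summary(mat, within=True).to_csv(out / "xcorr_node_summary.csv")
            results["xcorr"] = mat
        else:
            logger.warning("xcorr: no fitted events, stage skipped")
    return results


def fit_dose_table(
    table: pd.DataFrame,
    freq_model: str = "4pl",
    amp_model: str = "4pl",
    encoding_factor: float = 2.0,
) -> dict:
    """Fit frequency/amplitude concentration-response curves from a summary table.

    ``table`` columns: concentration (molar), frequency, amplitude.
    """
    freq = fit_curve(table.concentration, table.frequency, freq_model)
    amp = fit_curve(table.concentration, table.amplitude, amp_model)
    verdict = classify_encoding(freq, amp, factor=encoding_factor)
    return {"frequency": freq, "amplitude": amp, "verdict": verdict}


def concentration_series(
    config: SimulationConfig,
    concentrations: np.ndarray,
    agonist: str = "ACh",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate + detect one recording per concentration on a shared tissue.

    Frequency is the mean events/min over interior cells during exposure;
    amplitude is the mean detected event amplitude over interior-cell events.
    """
    base_seed = config.rng_seed if seed is None else seed
    root = np.random.default_rng(base_seed)
    streams = root.spawn(2 + len(concentrations))
    from .simulate import assign_sensitivities, generate_tessellation

    mask, _ = generate_tessellation(config, streams[0])
    tg = build_tissue_graph(mask)
    truth = assign_sensitivities(tg, config, streams[1])
    interior = set(tg.interior)
    rows = []
    for i, conc in enumerate(concentrations):
        traces, _true = simulate_traces(
            truth, tg, config, agonist=agonist, concentration=float(conc),
            rng=streams[2 + i],
        )
        events = detect_all_events(traces)
        exposure = (config.stimulus_onset, config.duration)
        summaries = summarize_cells(events, traces.cell_ids, exposure)
        sub = summaries.loc[summaries.index.isin(interior)]
        ev_int = events[events.cell_id.isin(interior)]
        rows.append(
            {
                "concentration": float(conc),
                "frequency": float(sub.frequency.mean()),
                "amplitude": float(ev_int.amplitude.mean()) if len(ev_int) else np.nan,
                "n_events": int(len(ev_int)),
            }
        )
    return pd.DataFrame(rows)


def encoding_experiment(
    config: SimulationConfig,
    concentrations: np.ndarray | None = None,
    agonist: str = "ACh",
    seed: int | None = None,
    encoding_factor: float = 2.0,
    n_replicates: int = 1,
) -> dict:
    """End-to-end encoding classification for simulated vessels.

    Venous mode fits 4PL curves to both modalities; arterial mode fits a 4PL
    to amplitude and a bell to frequency (its rate response rises then
    saturates/declines). With ``n_replicates`` > 1 the per-concentration
    summaries are averaged over independently simulated vessels before
    fitting, the way concentration-response studies average over animals
    before fitting the group curve.
    """
    if concentrations is None:
        concentrations = np.logspace(-9, -5, 7)
    base_seed = config.rng_seed if seed is None else seed
    rep_seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    tables = [
        concentration_series(config, concentrations, agonist=agonist, seed=int(s))
        for s in rep_seeds
    ]
    table = tables[0][["concentration"]].copy()
    for col in ("frequency", "amplitude"):
        table[col] = np.mean([t[col].to_numpy() for t in tables], axis=0)
    table["n_events"] = np.sum([t["n_events"].to_numpy() for t in tables], axis=0)
    freq_model = "4pl" if config.drive_curve.mode == "venous" else "bell"
    fits = fit_dose_table(table, freq_model=freq_model, amp_model="4pl",
                          encoding_factor=encoding_factor)
    fits["table"] = table
    fits["replicates"] = tables
    return fits


def overlap_experiment(
    config: SimulationConfig, seed: int | None = None, run_config: RunConfig | None = None
) -> dict:
    """Detect -> rank -> overlap chain for both agonists on one tissue."""
    cfg = run_config or RunConfig()
    ds = simulate_dataset(config, agonists=AGONISTS, seed=seed)
    tg = ds["tissue"]
    responders = {}
    for agonist in AGONISTS:
        bundle = analyze_dataset(ds["traces"][agonist], tg, cfg, agonist=agonist)
        responders[agonist] = set(bundle["responders"].cells)
    summary = overlap_analysis(
        responders[AGONISTS[0]], responders[AGONISTS[1]], len(tg.interior)
    )
    return {"dataset": ds, "responders": responders, "overlap": summary}


def within_between_correlation(
    config: SimulationConfig,
    seed: int | None = None,
    run_config: RunConfig | None = None,
    max_cells: int = 25,
) -> dict:
    """Intra- vs inter-agonist node connectivity on one simulated field.

    Responder traces from each agonist's recording are compared within the
    same responder set and across the two sets; node summaries are the 75th
    percentiles of the pairwise coefficients.
    """
    cfg = run_config or RunConfig()
    ds = simulate_dataset(config, agonists=AGONISTS, seed=seed)
    tg = ds["tissue"]
    bundles = {
        ag: analyze_dataset(ds["traces"][ag], tg, cfg, agonist=ag) for ag in AGONISTS
    }
    all_events = pd.concat([bundles[ag]["events"] for ag in AGONISTS], ignore_index=True)
    max_lag_s = compute_window(all_events, cfg.window_mult)
    segs = align_and_window([ds["traces"][ag] for ag in AGONISTS],
                            events=[bundles[ag]["events"] for ag in AGONISTS])
    seg = dict(zip(AGONISTS, segs))
    cells, cols = {}, {}
    for ag in AGONISTS:
        cells[ag] = sorted(bundles[ag]["responders"].cells)[:max_cells]
        cols[ag] = [ds["traces"][ag].cell_ids.index(c) for c in cells[ag]]
    lag = int(round(max_lag_s * config.frame_rate))
    a, b = AGONISTS
    within = correlation_matrix(seg[a][:, cols[a]], None, lag, cells[a])
    between = correlation_matrix(
        seg[a][:, cols[a]], seg[b][:, cols[b]], lag, cells[a], cells[b]
    )
    return {
        "within": connectivity_summary(within, within=True),
        "between": connectivity_summary(between, within=False),
        "within_matrix": within,
        "between_matrix": between,
    }
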