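"""End-to-end convenience pipelines and benchmark drivers.

These functions wire the modules together the way the benchmark studies
run them: simulate a scenario, polarize by the outgroup, attach the map,
classify, fit the HMM, decode, match lineages, and (for history studies)
fit the wave model on length-filtered tracts per lineage.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import evaluate, history, iohub, matcher, seeker, simulate


def prepare_panel(cfg: simulate.ScenarioConfig):
    """Simulate and run the standard preprocessing for one scenario."""
    panel, truth = simulate.simulate_panel(cfg)
    pp = iohub.polarize(panel, "outgroup")
    pp = iohub.attach_genetic_map(pp, simulate.scenario_map(cfg))
    return pp, truth


def seek_segments(panel, init: seeker.HMMParams | None = None):
    """Classify, fit the HMM by EM and decode archaic segments."""
    obs, haps = seeker.classify_all(panel)
    params = seeker.em_fit(obs, panel, init=init)
    segments = seeker.decode_segments(obs, panel, params, haps)
    return segments, params


def run_detection(cfg: simulate.ScenarioConfig):
    """Full detection pass; returns (panel, truth, segments, params)."""
    pp, truth = prepare_panel(cfg)
    segments, params = seek_segments(pp)
    return pp, truth, segments, params


def detection_metrics(cfg: simulate.ScenarioConfig) -> dict[str, float]:
    """Length-based and AIM-restricted concordance for one replicate."""
    pp, truth, segments, _ = run_detection(cfg)
    out: dict[str, float] = {}
    for basis in ("length", "aim"):
        r = evaluate.concordance(segments, truth, pp, basis=basis)
        out[f"{basis}_precision"] = r.precision
        out[f"{basis}_tpr"] = r.tpr
        out[f"{basis}_fpr"] = r.fpr
    return out


def detection_medians(configs) -> dict[str, float]:
    """Median metrics over a replicate set of scenario configs."""
    rows = [detection_metrics(cfg) for cfg in configs]
    return {k: float(np.median([r[k] for r in rows])) for k in rows[0]}


def standard_replicates(seeds, length_bp: int = 10_000_000,
                        n_test: int = 20) -> list[simulate.ScenarioConfig]:
    return [simulate.standard_scenario(int(s), length_bp=length_bp,
                                       n_test=n_test) for s in seeds]


def unknown_replicates(seeds, t_split_kya: float = 610.0,
                       length_bp: int = 10_000_000,
                       n_test: int = 20) -> list[simulate.ScenarioConfig]:
    return [simulate.unknown_lineage_scenario(int(s), t_split_kya=t_split_kya,
                                              length_bp=length_bp,
                                              n_test=n_test) for s in seeds]


def matching_accuracy_two_lineage(seed: int, min_bp: int = 15_000,
                                  length_bp: int = 20_000_000,
                                  n_test: int = 20) -> tuple[float, int]:
    """Fraction of truth tracts (>= min_bp) matched to the true lineage."""
    cfg = simulate.two_lineage_scenario(seed, length_bp=length_bp,
                                        n_test=n_test)
    pp, truth = prepare_panel(cfg)
    t = truth.table
    t = t[(t["end"] - t["start"]) >= min_bp]
    segments = [iohub.Segment(pp.chrom, int(r.start), int(r.end), r.haplotype)
                for _, r in t.iterrows()]
    results = matcher.match_segments(segments, pp)
    ok = sum(r.label == lin for r, lin in zip(results, t["lineage"]))
    return ok / len(results), len(results)


def infer_history(cfg: simulate.ScenarioConfig, segments, lineage: str,
                  min_bp: int = 15_000, K_max: int = 3,
                  seed: int = 0, screen_B: int = 20) -> history.WaveModel:
    """Wave-model selection on the decoded segments of one lineage.

    Same-haplotype segments separated by less than the detection floor
    are merged first.  When more than one wave is selected, waves with
    tiny contributions and weak bootstrap support are screened out and
    the model refitted with the reduced wave count.
    """
    lin_segs = [s for s in segments if s.label == lineage]
    lin_segs = history.merge_close_segments(lin_segs, max_gap=min_bp)
    frac = sum(s.length for s in lin_segs if s.length >= min_bp) \
        / (cfg.n_test * cfg.length_bp)
    sample = history.filter_and_convert(
        lin_segs, simulate.scenario_map(cfg), min_bp=min_bp,
        lineage=lineage, total_ancestry=frac)
    model = history.select_num_waves(sample, K_max=K_max, seed=seed)
    if model.K > 1 and screen_B > 0:
        ci = history.bootstrap_ci(sample, model, B=screen_B, seed=seed,
                                  K_max=K_max)
        flags = history.flag_unstable_waves(model, ci)
        if any(flags):
            model = history.fit_waves_em(sample, model.K - sum(flags),
                                         seed=seed)
    return model


def history_success(cfg: simulate.ScenarioConfig,
                    tol_time: float = 0.3, tol_prop: float = 0.5) -> bool:
    """End-to-end run of one scenario scored by wave-model success.

    For unknown-lineage scenarios every non-AMH, non-ILS segment counts
    toward the (single) introgressing lineage; otherwise segments are
    grouped by matched lineage label.
    """
    pp, truth, segments, _ = run_detection(cfg)
    matcher.match_segments(segments, pp)
    lineages = {lin for lin, _, _ in cfg.waves}
    try:
        if len(lineages) == 1:
            # single introgressing source: every archaic-side segment
            # belongs to it regardless of how deep its placement landed
            (lin,) = lineages
            keep = [s for s in segments
                    if s.label not in (matcher.LABEL_AMH, matcher.LABEL_ILS,
                                       matcher.LABEL_ROOT, None)]
            for s in keep:
                s.label = lin
            model = infer_history(cfg, keep, lin, seed=cfg.seed)
            truth_waves = [(t, m) for _, t, m in cfg.waves]
            return evaluate.model_success(model, truth_waves, tol_time, tol_prop)
        for lin in lineages:
            model = infer_history(cfg, segments, lin, seed=cfg.seed)
            truth_waves = [(t, m) for l, t, m in cfg.waves if l == lin]
            if not evaluate.model_success(model, truth_waves, tol_time,
                                          tol_prop):
                return False
        return True
    except (ValueError, RuntimeError):
        return False


def history_success_rate(family: str, seed: int,
                         length_bp: int | None = None,
                         n_test: int | None = None) -> tuple[float, int]:
    """Success fraction over one preset scenario family."""
    configs = simulate.preset_scenarios(family, seed=seed)
    if length_bp is not None or n_test is not None:
        configs = [replace(c,
                           length_bp=length_bp or c.length_bp,
                           n_test=n_test or c.n_test) for c in configs]
    ok = sum(history_success(cfg) for cfg in configs)
    return ok / len(configs), len(configs)
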