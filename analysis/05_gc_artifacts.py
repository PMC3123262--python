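#!/usr/bin/env python
"""GC context of false-positive calls: genomic-wave vs wave-free nulls.

Finding: when self tracks carry a GC-correlated wave, essentially all
false-positive events fall in GC-rich neighbourhoods (positive GC excess
over the genome average), mirroring the observation that recurrent
large-event calls sat in regions of elevated GC. Wave-free null calls show
no GC preference. An optional loess wave-correction pass removes most
wave-driven calls.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from acgh.caller import CallingCriterion, call_events, segment_track
from acgh.gc import probe_gc, region_vs_genome
from acgh.preprocess import gc_wave_correct
from acgh.simulate import HybridizationSpec, make_genome, make_probe_map, simulate_hybridization

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-tracks", type=int, default=15)
    ap.add_argument("--wave", type=float, default=4.0)
    args = ap.parse_args()

    genome = make_genome({f"chr{i + 1}": 2_000_000 for i in range(5)}, seed=args.seed)
    pmap = make_probe_map(genome, mean_spacing=1200, seed=args.seed)
    gc = probe_gc(genome, pmap)
    root = np.random.default_rng(args.seed)

    wave_events, corrected_events = [], []
    for i in range(args.n_tracks):
        spec = HybridizationSpec(f"Self{i + 1}", "self", noise_sd=0.2,
                                 wave_coefficient=args.wave,
                                 seed=int(root.integers(2**31)))
        track, _ = simulate_hybridization(pmap, genome, spec)
        wave_events.extend(call_events(segment_track(track), track))
        fixed = gc_wave_correct(track, gc)
        corrected_events.extend(call_events(segment_track(fixed), fixed))

    null_events = []
    for i in range(4 * args.n_tracks):
        spec = HybridizationSpec(f"Self{i + 1}", "self", noise_sd=0.2,
                                 seed=int(root.integers(2**31)))
        track, _ = simulate_hybridization(pmap, None, spec)
        null_events.extend(call_events(segment_track(track, penalty=0.135),
                                       track, CallingCriterion(0.3, 3)))

    df_wave = region_vs_genome(wave_events, genome)
    df_null = region_vs_genome(null_events, genome)
    frac_pos = float((df_wave["excess"] > 0).mean()) if len(df_wave) else float("nan")

    print(f"genome GC: {genome.gc_fraction:.4f}")
    print(f"wave (coef {args.wave}) false calls: {len(df_wave)}; "
          f"{100 * frac_pos:.0f}% with positive GC excess "
          f"(mean excess {df_wave['excess'].mean():+.3f})")
    print(f"after loess wave correction: {len(corrected_events)} calls remain "
          f"({len(wave_events) - len(corrected_events)} removed)")
    print(f"wave-free null calls at (0.3, 3): {len(df_null)}; "
          f"mean GC excess {df_null['excess'].mean():+.4f}")

    (ROOT / "results").mkdir(exist_ok=True)
    df_wave.to_csv(ROOT / "results" / "gc_excess_wave_calls.tsv",
                   sep="\t", index=False)
    (ROOT / "results" / "gc_artifacts.json").write_text(json.dumps({
        "genome_gc": round(genome.gc_fraction, 4),
        "wave_coefficient": args.wave,
        "wave_calls": len(df_wave),
        "wave_calls_positive_excess_pct": round(100 * frac_pos, 1),
        "wave_calls_mean_excess": round(float(df_wave["excess"].mean()), 4),
        "wave_calls_after_correction": len(corrected_events),
        "null_calls": len(df_null),
        "null_calls_mean_excess": round(float(df_null["excess"].mean()), 4),
    }, indent=2))
    print("wrote results/gc_excess_wave_calls.tsv, gc_artifacts.json")


if __name__ == "__main__":
    main()
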