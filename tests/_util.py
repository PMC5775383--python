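"""Shared helpers for the test suite: trace-level simulation shortcuts and
truth matching."""

from dataclasses import replace

import numpy as np

from anchortrack.chip_model import build_layout
from anchortrack.synthetic_timelapse import PRESETS, generate_population

FINAL_TIME_H = 62.0
MEASUREMENT_NOISE_SD = 2.0  # counts, matches default read noise averaged over a mask


def final_deltas(
    preset=None,
    seed=0,
    rows=30,
    cols=30,
    noise_sd=MEASUREMENT_NOISE_SD,
    t_final=FINAL_TIME_H,
    **preset_overrides,
):
    """Simulate final Delta I values directly from generator ground truth.

    Bypasses image rendering: Delta I_final = slope * t + measurement noise,
    which is exactly what the imaging pipeline measures up to a constant
    blur attenuation.  Returns (finals, is_hp) for viable cells.
    """
    preset = preset or PRESETS["R5"]
    if preset_overrides:
        preset = replace(preset, **preset_overrides)
    layout = build_layout(rows=rows, cols=cols)
    truths = generate_population(layout, preset, seed)
    rng = np.random.default_rng(seed + 100_003)
    slopes = np.array([t.slope for t in truths if t.is_viable])
    is_hp = np.array([t.is_hp for t in truths if t.is_viable], dtype=bool)
    finals = slopes * t_final + rng.normal(0.0, noise_sd, slopes.size)
    return finals, is_hp


def match_traces_to_truth(traces, truths):
    """Map each trace to the unique viable truth cell in its anchor.

    Traces come from anchors with exactly one frame-0 detection; anchors
    where that mapping is ambiguous (several viable truth cells) are
    skipped.  Returns a list of (trace, truth) pairs.
    """
    by_anchor = {}
    for t in truths:
        if t.is_viable:
            by_anchor.setdefault(t.anchor_id, []).append(t)
    pairs = []
    for tr in traces:
        candidates = by_anchor.get(tr.anchor_id, [])
        if len(candidates) == 1:
            pairs.append((tr, candidates[0]))
    return pairs
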