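import warnings

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from anchortrack.pipeline import RunConfig, analyze_stack
from anchortrack.synthetic_timelapse import generate_population, render_frame


@pytest.fixture(scope="session")
def r5_chip():
    """One fully analysed default-noise 16x16 chip (R5 preset, fixed seed).

    Shared by segmentation/kinetics/classification recovery tests so the
    rendering cost is paid once.
    """
    cfg = RunConfig(preset="R5", seed=3, rows=16, cols=16)
    layout, preset, imaging = cfg.layout(), cfg.condition(), cfg.imaging()
    truths = generate_population(layout, preset, cfg.seed)
    n = len(imaging.time_grid_h)
    reds = (
        render_frame(truths, layout, k, "red_tracker", imaging, cfg.seed)
        for k in range(n)
    )
    greens = (
        render_frame(truths, layout, k, "green_gfp", imaging, cfg.seed)
        for k in range(n)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traces, detections = analyze_stack(
            reds, greens, layout, imaging.time_grid_h, cfg.pixel_size_um
        )
    return {
        "config": cfg,
        "layout": layout,
        "preset": preset,
        "imaging": imaging,
        "truths": truths,
        "traces": traces,
        "detections": detections,
    }
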