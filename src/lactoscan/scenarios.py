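"""Canonical benchmark scenarios: parameter-recovery runs on synthetic scenes.

Real AO-stained milk slides are not redistributable, so the package's
end-to-end checks run the full pipeline on synthetic whole-slide scenes
whose ground truth is constructed to hold a known crescent incidence or a
known cellular share of integrated RNA, and ask how well the pipeline
recovers the configured value.
"""

from __future__ import annotations

from .quantify import MilkSummary, process_stack
from .segment import SegmentationParams
from .synthetic import SceneParams, generate_scene, render_channels

__all__ = ["run_incidence_recovery", "run_share_recovery"]

#: Whole-slide scene geometry: 20,000 globules on a 4096 px square field,
#: radius lognormal(median 5 px, sigma 0.15) — a density comfortably below
#: the rejection-sampling packing limit — with default blur and noise.
WHOLE_SLIDE = dict(
    width=4096,
    height=4096,
    n_globules=20_000,
    globule_radius_lognormal=(5.0, 0.15),
    n_cells=50,
    # 8 px edge-to-edge gap leaves 4 px between detected rims, beyond the
    # reach of the 3x3 closing, so neighbouring globules never merge
    min_separation=8.0,
)

#: Fixed fluorescence thresholds for calibrated-share scenes, whose cell and
#: crescent amplitudes may differ by orders of magnitude; a bimodal (Otsu)
#: threshold would land between the two foreground classes and erase the
#: dimmer one.  Backgrounds sit at 10 with noise sigma 2, so 20 is a
#: comfortable 5-sigma floor.
FIXED_FLUOR = SegmentationParams(
    threshold_method="fixed", fixed_thresholds={"rna": 20.0, "dna": 20.0}
)


def run_incidence_recovery(incidence_pct: float, seed: int) -> MilkSummary:
    """Full pipeline on a whole-slide scene with an exact crescent count.

    The number of crescent-bearing globules is fixed to
    ``round(incidence_pct/100 * 20000)``, so a perfect detector reports
    exactly ``incidence_pct`` percent of globules with crescents.
    """
    n = WHOLE_SLIDE["n_globules"]
    k = round(incidence_pct / 100.0 * n)
    params = SceneParams(crescent_incidence=int(k), seed=seed, **WHOLE_SLIDE)
    scene = generate_scene(params)
    stack = render_channels(scene)
    return process_stack(stack).summary


def run_share_recovery(share_pct: float, seed: int) -> MilkSummary:
    """Full pipeline on a scene calibrated to a known cellular RNA share.

    A 512x512 field with 200 globules and 20 nucleated cells; the cell and
    crescent RNA amplitudes are derived so the ground-truth cellular share
    of integrated RNA equals ``share_pct`` percent exactly.
    """
    params = SceneParams(
        n_cells=20, cellular_share_target=share_pct / 100.0, seed=seed
    )
    scene = generate_scene(params)
    stack = render_channels(scene)
    return process_stack(stack, seg=FIXED_FLUOR).summary
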