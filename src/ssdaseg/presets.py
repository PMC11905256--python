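"""Ablation presets: which of the three components each named setting enables.

The grid follows the component-ablation design: a joint-training baseline
with none of the additions, four partial combinations, and the full
method.  ``tl_only`` is the supervised-only reference that sees nothing
but the small labeled target subset (it keeps the architectural modules —
it ablates the *data*, not the network).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "LABELED_RATIOS"]

LABELED_RATIOS = (0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    use_glf: bool
    use_sad: bool
    use_semt: bool
    use_source: bool = True     # joint training uses SL; tl_only does not

    @property
    def description(self) -> str:
        def mark(b):
            return "+" if b else "-"
        return (f"GLF{mark(self.use_glf)} SAD{mark(self.use_sad)} "
                f"SEMT{mark(self.use_semt)} SRC{mark(self.use_source)}")


PRESETS: dict[str, ExperimentPreset] = {
    # joint SL+TL supervised training, no GLF / SAD / SE-MT additions
    "baseline": ExperimentPreset("baseline", False, False, False),
    "comb1": ExperimentPreset("comb1", False, False, True),
    "comb2": ExperimentPreset("comb2", True, False, True),
    "comb3": ExperimentPreset("comb3", False, True, True),
    # GLF+SAD without SE-MT: joint training on SL+TL only (no TU)
    "comb4": ExperimentPreset("comb4", True, True, False),
    "full": ExperimentPreset("full", True, True, True),
    # supervised-only reference: full architecture, TL data only
    "tl_only": ExperimentPreset("tl_only", True, True, False, use_source=False),
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
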