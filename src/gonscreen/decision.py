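"""The decision record both classifier branches emit and the ensemble routes."""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic import GLAUCOMA, NORMAL


@dataclass(frozen=True)
class ClassifierDecision:
    """Binary decision with its confidence score.

    ``confidence`` is the max-class probability (never below 0.5 for a binary
    classifier); the label is glaucoma whenever ``p_glaucoma >= 0.5`` (the tie
    at exactly 0.5 resolves to glaucoma — screening errs toward referral).
    """

    label: str
    confidence: float
    p_glaucoma: float
    source: str  # "cnn" | "svm"

    @classmethod
    def from_p_glaucoma(cls, p: float, source: str) -> "ClassifierDecision":
        p = float(p)
        label = GLAUCOMA if p >= 0.5 else NORMAL
        return cls(label=label, confidence=max(p, 1.0 - p), p_glaucoma=p,
                   source=source)

    def __post_init__(self):
        assert self.source in ("cnn", "svm")
        assert abs(self.confidence - max(self.p_glaucoma, 1 - self.p_glaucoma)) < 1e-9
        assert (self.label == GLAUCOMA) == (self.p_glaucoma >= 0.5)
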