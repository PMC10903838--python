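"""Quality-control verdicts.

QC failures are data, not exceptions: a cohort run records the verdict and
continues, mirroring how studies exclude subjects with failed segmentation
or registration rather than aborting.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class QCVerdict:
    passed: bool
    reasons: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.passed

    def to_dict(self) -> dict:
        return {"passed": self.passed, "reasons": list(self.reasons), "metrics": dict(self.metrics)}
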