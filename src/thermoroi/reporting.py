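"""Per-stage outcome reporting shared by the three pipelines.

A stage failure is recorded, not raised, so that later stages can still
run where they do not depend on the failed one, and callers get a partial
ROI set plus a machine-readable account of what went wrong where.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["StageRecord", "PipelineReport", "ExtractionResult"]


@dataclass
class StageRecord:
    stage: str
    ok: bool
    message: str = ""


@dataclass
class PipelineReport:
    region: str
    stages: list[StageRecord] = field(default_factory=list)
    missing_labels: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, ok: bool, message: str = "") -> None:
        self.stages.append(StageRecord(stage, ok, message))

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    @property
    def failed_stage(self) -> str | None:
        for s in self.stages:
            if not s.ok:
                return s.stage
        return None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None and not self.missing_labels

    def to_dict(self) -> dict[str, Any]:
        return {
            "region": self.region,
            "ok": self.ok,
            "failed_stage": self.failed_stage,
            "stages": [{"stage": s.stage, "ok": s.ok, "message": s.message}
                       for s in self.stages],
            "missing_labels": list(self.missing_labels),
            "warnings": list(self.warnings),
        }


@dataclass
class ExtractionResult:
    """A (possibly partial) ROI set together with its stage report and
    the foreground segmentation the ROIs were clipped to."""

    roi_set: "Any"              # thermal_io.ROISet
    report: PipelineReport
    foreground: "Any" = None    # thermal_io.BinaryMask | None
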