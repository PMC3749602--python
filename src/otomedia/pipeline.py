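"""End-to-end orchestration: image -> preprocess -> vocabulary -> grammar."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import REJECTED, FeatureVector, PipelineConfig, load_image
from .grammar import GrammarThresholds, classify_with_trace
from .preprocess import correct_specular, detect_specular, segment_membrane, should_reject
from .vocabulary import ColorClusterModel, extract_features

__all__ = ["PipelineResult", "run_pipeline", "summarize_results"]

log = logging.getLogger("otomedia")


@dataclass
class PipelineResult:
    """Per-image outcome of the full diagnostic pipeline.

    Rejected images carry no feature vector; non-rejected results carry all
    eight features and the trace of grammar rules that fired.  ``error``
    holds a message when processing failed (the batch is never aborted).
    """

    source_id: str
    diagnosis: str | None
    features: FeatureVector | None = None
    highlight: dict = field(default_factory=dict)
    stage_trace: list[str] = field(default_factory=list)
    config_fingerprint: str = ""
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "diagnosis": self.diagnosis,
            "features": None if self.features is None else self.features.as_dict(),
            "highlight": self.highlight,
            "stage_trace": self.stage_trace,
            "config_fingerprint": self.config_fingerprint,
            "error": self.error,
        }


def _process_one(
    image: np.ndarray,
    source_id: str,
    config: PipelineConfig,
    translucent_model: ColorClusterModel,
    amber_model: ColorClusterModel,
    thresholds: GrammarThresholds,
    mask: np.ndarray | None,
) -> PipelineResult:
    fp = config.fingerprint()
    if mask is None:
        seg = segment_membrane(image, config, source_id=source_id)
    else:
        from .core import SegmentedImage

        seg = SegmentedImage(image=image, mask=mask, source_id=source_id)
    report = detect_specular(seg, config.specular_threshold)
    highlight = {
        "largest_fraction": report.largest_fraction,
        "n_components": len(report.components),
    }
    if should_reject(report, config.reject_fraction):
        log.info("%s: rejected (largest highlight %.3f of membrane)",
                 source_id, report.largest_fraction)
        return PipelineResult(
            source_id=source_id, diagnosis=REJECTED, highlight=highlight,
            config_fingerprint=fp,
        )
    seg = correct_specular(seg, report)
    fv = extract_features(seg, translucent_model, amber_model, config)
    label, trace = classify_with_trace(fv, thresholds)
    log.info("%s: %s (%s)", source_id, label, "; ".join(trace))
    return PipelineResult(
        source_id=source_id, diagnosis=label, features=fv, highlight=highlight,
        stage_trace=trace, config_fingerprint=fp,
    )


def run_pipeline(
    inputs,
    config: PipelineConfig,
    translucent_model: ColorClusterModel,
    amber_model: ColorClusterModel,
    thresholds: GrammarThresholds,
    masks=None,
) -> list[PipelineResult]:
    """Run the full pipeline over a batch.

    ``inputs`` is a list of image paths or of ``(array, source_id)`` pairs;
    ``masks`` optionally bypasses segmentation with known membrane masks
    (parallel list).  Per-image failures are logged and captured in the
    result's ``error`` field without aborting the batch.
    """
    results: list[PipelineResult] = []
    for i, item in enumerate(inputs):
        if isinstance(item, (str, Path)):
            source_id = str(item)
            loader = lambda it=item: load_image(it)
        else:
            arr, source_id = item
            loader = lambda a=arr: np.asarray(a, dtype=float)
        mask = None if masks is None else masks[i]
        try:
            image = loader()
            results.append(
                _process_one(image, source_id, config, translucent_model,
                             amber_model, thresholds, mask)
            )
        except Exception as exc:
            log.exception("%s: pipeline failure", source_id)
            results.append(
                PipelineResult(source_id=source_id, diagnosis=None,
                               config_fingerprint=config.fingerprint(),
                               error=str(exc))
            )
    return results


def summarize_results(results: list[PipelineResult]) -> dict:
    """Batch summary: label counts, rejected fraction, failures."""
    n = len(results)
    counts: dict[str, int] = {}
    for r in results:
        key = r.diagnosis if r.error is None else "ERROR"
        counts[key] = counts.get(key, 0) + 1
    rejected = counts.get(REJECTED, 0)
    return {
        "n": n,
        "counts": counts,
        "rejected_fraction": rejected / n if n else 0.0,
    }
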