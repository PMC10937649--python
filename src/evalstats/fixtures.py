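"""Embedded worked-example fixtures.

These small constant inputs come from published worked examples of chest
X-ray classification and PET tumour segmentation: a 2x2 confusion matrix
of a binary COVID-19 classifier (600 test X-rays), a 4x4 confusion matrix
of a four-class lung-infection classifier (560 test X-rays), the
discordant-pair counts comparing two classifiers' sensitivity and
specificity, and the pixel counts of a 128x128 tumour-mask comparison.
They make the whole metric catalogue runnable and checkable without any
image data or trained model.

The tumour-mask *geometry* is synthetic: only the four pixel counts are
published, and every metric computed from the masks here depends on the
counts alone, so the masks are laid out as a compact synthetic blob that
realizes exactly those counts.
"""

from __future__ import annotations

import numpy as np

from .confusion import BinaryConfusion, ConfusionMatrixK
from .errors import InputError
from .segmentation import Mask
from .stattests import DiscordantPair

__all__ = ["FIXTURE_NAMES", "load_fixture"]

# Binary confusion of the U-Net COVID-19 classifier: 300 positive and 300
# negative chest X-rays (printed Predicted\True; counts are orientation-free).
_TABLE1 = dict(tp=261, tn=193, fp=107, fn=39)

# 4x4 confusion (rows = true class) of the four-class X-ray classifier:
# negative / COVID-19 / pneumonia / tuberculosis, 140 X-rays per class.
_TABLE2 = (
    (120, 7, 9, 4),
    (15, 116, 3, 6),
    (12, 13, 115, 0),
    (2, 96, 4, 38),
)
_TABLE2_CLASSES = ("negative", "covid19", "pneumonia", "tuberculosis")

# Discordant counts between the two classifiers: b = misclassified by the
# first only, c = by the second only; among positives (sensitivity) and
# negatives (specificity) separately.
_TABLE3_COVID = dict(b=54, c=19)
_TABLE3_NEGATIVE = dict(b=44, c=24)

# Pixel counts of the 128x128 tumour-mask comparison.
_FIG2_COUNTS = dict(tp=181, tn=16156, fp=17, fn=30)
_FIG2_SHAPE = (128, 128)

FIXTURE_NAMES = (
    "table1_confusion",
    "table2_confusion_4x4",
    "table3_discordant_covid",
    "table3_discordant_negative",
    "fig2_mask_counts",
    "fig2_masks",
)


def _fig2_masks() -> tuple[Mask, Mask]:
    """Synthetic 128x128 mask pair realizing the published pixel counts.

    The published figure gives only TP/TN/FP/FN pixel counts, so the masks
    are laid out as a compact rectangle-based blob: a shared core of TP
    pixels, an FN fringe present only in the ground truth, and an FP fringe
    present only in the prediction.  All overlap metrics depend only on
    the counts, which are reproduced exactly.
    """
    tp, fp, fn = _FIG2_COUNTS["tp"], _FIG2_COUNTS["fp"], _FIG2_COUNTS["fn"]
    truth = np.zeros(_FIG2_SHAPE, dtype=np.int8)
    pred = np.zeros(_FIG2_SHAPE, dtype=np.int8)
    flat_t = truth.reshape(-1)
    flat_p = pred.reshape(-1)
    # centre the blob: start near the middle row of the image
    start = 60 * 128 + 40
    flat_t[start : start + tp] = 1  # shared TP core
    flat_p[start : start + tp] = 1
    flat_t[start + tp : start + tp + fn] = 1  # truth-only fringe
    flat_p[start + tp + fn : start + tp + fn + fp] = 1  # prediction-only fringe
    return Mask(truth), Mask(pred)


def load_fixture(name: str):
    """Return the typed object for a named embedded fixture.

    ``table1_confusion`` -> BinaryConfusion; ``table2_confusion_4x4`` ->
    ConfusionMatrixK; ``table3_discordant_covid`` /
    ``table3_discordant_negative`` -> DiscordantPair;
    ``fig2_mask_counts`` -> BinaryConfusion of pixel counts;
    ``fig2_masks`` -> (ground truth Mask, predicted Mask).
    """
    if name == "table1_confusion":
        return BinaryConfusion(**_TABLE1)
    if name == "table2_confusion_4x4":
        return ConfusionMatrixK.from_counts(
            _TABLE2, class_names=_TABLE2_CLASSES, orientation="true_rows"
        )
    if name == "table3_discordant_covid":
        return DiscordantPair(**_TABLE3_COVID)
    if name == "table3_discordant_negative":
        return DiscordantPair(**_TABLE3_NEGATIVE)
    if name == "fig2_mask_counts":
        return BinaryConfusion(**_FIG2_COUNTS)
    if name == "fig2_masks":
        return _fig2_masks()
    raise InputError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
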