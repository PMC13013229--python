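"""Published cohort reference values for the 26-marker panel.

Pre- and post-treatment medians with interquartile ranges from the published
45-patient ATTR-CM treatment-response cohort (median with [q1; q3]).  These
are *input data* for the package: the cohort simulator uses them as the
default baseline medians and treatment-effect magnitudes, and the printed
median differences serve as arithmetic cross-checks.

Units: SUV for SUV metrics and retention index, SUV*mL for amyloid activity,
mL for affected volume.  The associated paired p values are reproduced for
completeness.
"""

from __future__ import annotations

from typing import Dict, NamedTuple

from .markers import MARKER_NAMES

__all__ = ["MarkerReference", "PUBLISHED_MARKER_TABLE", "published_median_difference"]


class MarkerReference(NamedTuple):
    pre_median: float
    pre_q1: float
    pre_q3: float
    post_median: float
    post_q1: float
    post_q3: float
    p_value: float  # paired pre/post test, unadjusted


# marker -> published pre/post medians (IQR) and paired p value
PUBLISHED_MARKER_TABLE: Dict[str, MarkerReference] = {
    "SUVmax_LV": MarkerReference(18.6, 14.9, 23.3, 14.1, 11.4, 16.4, 1e-4),
    "SUVmax_MYOCARDIUM": MarkerReference(19.5, 14.7, 25.6, 15.5, 11.8, 19.2, 1e-4),
    "SUVpeak_LV": MarkerReference(13.9, 11.0, 17.1, 10.0, 8.0, 12.9, 1e-4),
    "SUVpeak_MYOCARDIUM": MarkerReference(14.6, 10.3, 19.5, 12.2, 8.5, 14.5, 1e-4),
    "AMYLOID_ACTIVITY_MYOCARDIUM": MarkerReference(302.4, 229.2, 420.0, 239.5, 187.2, 322.0, 1e-4),
    "AMYLOID_ACTIVITY_LV": MarkerReference(124.4, 101.5, 191.0, 97.5, 75.2, 139.2, 1e-4),
    "SUVmax_LA": MarkerReference(7.3, 5.8, 8.8, 5.8, 5.0, 7.1, 1e-4),
    "SUVmean_LV": MarkerReference(6.1, 5.3, 9.0, 5.1, 3.8, 6.6, 1e-4),
    "SUVmean_MYOCARDIUM": MarkerReference(9.4, 7.5, 12.0, 7.3, 5.6, 9.3, 1e-4),
    "SUVmax_RV": MarkerReference(14.6, 11.6, 18.1, 11.7, 9.3, 14.3, 1e-4),
    "SUVmax_RA": MarkerReference(6.2, 5.0, 7.7, 5.1, 4.3, 5.8, 1e-4),
    "SUVpeak_RV": MarkerReference(9.5, 7.8, 12.2, 8.5, 6.5, 9.9, 1e-4),
    "SUVmean_RV": MarkerReference(4.9, 3.4, 5.4, 3.9, 3.0, 5.3, 1e-4),
    "RETENTION_INDEX": MarkerReference(4.4, 3.2, 7.2, 3.1, 2.4, 4.8, 1e-4),
    "AMYLOID_ACTIVITY_RV": MarkerReference(102.9, 75.7, 149.1, 89.4, 65.1, 123.7, 1e-4),
    "SUVpeak_LA": MarkerReference(4.6, 3.8, 5.8, 4.0, 3.4, 4.6, 1e-4),
    "SUVpeak_RA": MarkerReference(4.4, 3.6, 5.0, 3.5, 3.2, 4.3, 1e-4),
    "SUVmean_RA": MarkerReference(1.8, 1.5, 2.1, 1.9, 1.6, 2.2, 0.2006),
    "AFFECTED_VOLUME_MYOCARDIUM": MarkerReference(92.6, 60.3, 120.4, 93.8, 70.9, 115.3, 0.3817),
    "AMYLOID_ACTIVITY_LA": MarkerReference(29.7, 22.6, 35.9, 26.3, 22.1, 33.4, 0.3917),
    "SUVmean_LA": MarkerReference(2.1, 1.9, 2.6, 2.2, 1.9, 2.4, 0.5537),
    "AFFECTED_VOLUME_RA": MarkerReference(96.6, 69.7, 122.5, 90.2, 71.4, 119.6, 0.6712),
    "AMYLOID_ACTIVITY_RA": MarkerReference(24.4, 18.4, 33.7, 26.5, 20.3, 32.7, 0.6862),
    "AFFECTED_VOLUME_LA": MarkerReference(74.8, 65.2, 85.7, 77.5, 64.1, 85.8, 0.7176),
    "AFFECTED_VOLUME_RV": MarkerReference(118.6, 96.5, 135.7, 120.3, 102.5, 139.9, 0.7333),
    "AFFECTED_VOLUME_LV": MarkerReference(97.6, 85.8, 110.1, 92.8, 81.8, 115.1, 0.8477),
}

assert set(PUBLISHED_MARKER_TABLE) == set(MARKER_NAMES)


def published_median_difference(marker: str) -> float:
    """Pre-minus-post median difference for one marker, from the published table."""
    ref = PUBLISHED_MARKER_TABLE[marker]
    return ref.pre_median - ref.post_median
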