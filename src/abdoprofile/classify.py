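"""Interval-based classification of profile curves into the six profile types.

Three criteria are applied to the derived metrics:

* criterion I  (K2, InfArc)  -> raised (RP) / fallen (FP) profile,
* criterion II (K1, Area2)   -> flat (FTP) / prominent (PP) profile,
* criterion III (AntPr, InfPr) -> below/above-average projection bands,

plus the composite A/B "steatosic abdomen" types built from them.  The
interval bounds are empirical cohort ranges, not a partition: values falling
in the gaps (or outside every interval) are labeled ``indeterminate`` in the
default strict mode.  A ``nearest`` mode snaps gap values to the closest
interval instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import DomainError
from .geometry import ProfileMetrics

__all__ = [
    "ClassificationThresholds",
    "ProfileClassification",
    "classify_criterion1",
    "classify_criterion2",
    "classify_criterion3",
    "steatosis_types",
    "classify_profile",
]

RP, FP, FTP, PP = "RP", "FP", "FTP", "PP"
INDETERMINATE = "indeterminate"
BELOW, ABOVE, OUT = "below_average", "above_average", "out_of_range"
STEATOSIC, NON_STEATOSIC = "steatosic", "non_steatosic"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Printed interval bounds, in conventional display units.

    ``scale`` rescales length-type thresholds for digitizations at other
    resolutions: lengths scale by ``s``, areas by ``s**2`` and curvatures by
    ``1/s`` (see :meth:`rescaled`).
    """

    k2_rp_lo: float = 0.000493763
    k2_rp_hi: float = 0.027066286
    infarc_rp_lo: float = 108.0939
    infarc_rp_hi: float = 214.7204
    k2_fp_lo: float = 0.029424926
    k2_fp_hi: float = 0.080514181
    infarc_fp_lo: float = 225.8813
    infarc_fp_hi: float = 391.5648
    k1_ftp_lo: float = 0.000194215
    k1_ftp_hi: float = 0.005002445
    area2_ftp_lo: float = 7.56
    area2_ftp_hi: float = 94.89
    k1_pp_lo: float = 0.006819941
    k1_pp_hi: float = 0.014204314
    area2_pp_lo: float = 91.35
    area2_pp_hi: float = 187.54
    antpr_lo: float = 22.39
    antpr_split: float = 69.16
    antpr_hi: float = 115.9
    infpr_lo: float = 2.41
    infpr_split: float = 42.85
    infpr_hi: float = 108.88

    def __post_init__(self) -> None:
        intervals = [
            (self.k2_rp_lo, self.k2_rp_hi),
            (self.infarc_rp_lo, self.infarc_rp_hi),
            (self.k2_fp_lo, self.k2_fp_hi),
            (self.infarc_fp_lo, self.infarc_fp_hi),
            (self.k1_ftp_lo, self.k1_ftp_hi),
            (self.area2_ftp_lo, self.area2_ftp_hi),
            (self.k1_pp_lo, self.k1_pp_hi),
            (self.area2_pp_lo, self.area2_pp_hi),
            (self.antpr_lo, self.antpr_hi),
            (self.infpr_lo, self.infpr_hi),
        ]
        for lo, hi in intervals:
            if not lo < hi:
                raise DomainError(f"threshold interval [{lo}, {hi}] is empty")
        if not self.antpr_lo < self.antpr_split < self.antpr_hi:
            raise DomainError("antpr_split must lie inside [antpr_lo, antpr_hi]")
        if not self.infpr_lo < self.infpr_split < self.infpr_hi:
            raise DomainError("infpr_split must lie inside [infpr_lo, infpr_hi]")

    def rescaled(self, s: float) -> "ClassificationThresholds":
        """Thresholds for coordinates digitized at ``s`` times the reference scale."""
        if s <= 0.0:
            raise DomainError("scale factor must be positive")
        kw = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if name.startswith("k"):
                kw[name] = v / s
            elif name.startswith("area"):
                kw[name] = v * s * s
            else:
                kw[name] = v * s
        return ClassificationThresholds(**kw)


@dataclass(frozen=True)
class ProfileClassification:
    criterion1: str
    criterion2: str
    antpr_band: str
    infpr_band: str
    type_a: str
    type_b: str

    def as_dict(self) -> dict[str, str]:
        return {
            "criterion1": self.criterion1,
            "criterion2": self.criterion2,
            "antpr_band": self.antpr_band,
            "infpr_band": self.infpr_band,
            "type_a": self.type_a,
            "type_b": self.type_b,
        }


def _inside(v: float, lo: float, hi: float) -> bool:
    return lo <= v <= hi


def _interval_distance(v: float, lo: float, hi: float) -> float:
    """Gap to the interval, normalized by its width (0 when inside)."""
    if v < lo:
        return (lo - v) / (hi - lo)
    if v > hi:
        return (v - hi) / (hi - lo)
    return 0.0


def _pair_classify(
    v1: float,
    v2: float,
    boxes: dict[str, tuple[tuple[float, float], tuple[float, float]]],
    mode: str,
) -> str:
    hits = [
        label
        for label, (iv1, iv2) in boxes.items()
        if _inside(v1, *iv1) and _inside(v2, *iv2)
    ]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:  # overlapping printed intervals cannot both hold here
        return INDETERMINATE
    if mode == "nearest":
        dists = {
            label: _interval_distance(v1, *iv1) + _interval_distance(v2, *iv2)
            for label, (iv1, iv2) in boxes.items()
        }
        best = min(dists, key=dists.get)
        ties = [k for k, d in dists.items() if d == dists[best]]
        return best if len(ties) == 1 else INDETERMINATE
    return INDETERMINATE


def classify_criterion1(
    k2: float,
    inf_arc: float,
    th: ClassificationThresholds | None = None,
    mode: str = "strict",
) -> str:
    """Raised vs fallen profile from the inferior curvature and arc length."""
    th = th or ClassificationThresholds()
    if k2 < 0.0 or inf_arc < 0.0:
        raise DomainError("k2 and inf_arc must be non-negative")
    return _pair_classify(
        k2,
        inf_arc,
        {
            RP: ((th.k2_rp_lo, th.k2_rp_hi), (th.infarc_rp_lo, th.infarc_rp_hi)),
            FP: ((th.k2_fp_lo, th.k2_fp_hi), (th.infarc_fp_lo, th.infarc_fp_hi)),
        },
        mode,
    )


def classify_criterion2(
    k1: float,
    area2: float,
    th: ClassificationThresholds | None = None,
    mode: str = "strict",
) -> str:
    """Flat vs prominent profile from the superior curvature and lower area.

    The printed Area2 intervals overlap on [91.35, 94.89]; because the K1
    intervals are disjoint, K1 membership is decisive there.
    """
    th = th or ClassificationThresholds()
    if k1 < 0.0 or area2 < 0.0:
        raise DomainError("k1 and area2 must be non-negative")
    return _pair_classify(
        k1,
        area2,
        {
            FTP: ((th.k1_ftp_lo, th.k1_ftp_hi), (th.area2_ftp_lo, th.area2_ftp_hi)),
            PP: ((th.k1_pp_lo, th.k1_pp_hi), (th.area2_pp_lo, th.area2_pp_hi)),
        },
        mode,
    )


def _band(v: float, lo: float, split: float, hi: float) -> str:
    if not lo <= v <= hi:
        return OUT
    return BELOW if v < split else ABOVE  # boundary goes to the upper band


def classify_criterion3(
    ant_pr: float,
    inf_pr: float,
    th: ClassificationThresholds | None = None,
) -> tuple[str, str]:
    """Below/above-average bands for the anterior and inferior projections."""
    th = th or ClassificationThresholds()
    return (
        _band(ant_pr, th.antpr_lo, th.antpr_split, th.antpr_hi),
        _band(inf_pr, th.infpr_lo, th.infpr_split, th.infpr_hi),
    )


def steatosis_types(
    criterion1: str, criterion2: str, antpr_band: str, infpr_band: str
) -> tuple[str, str]:
    """Composite A/B steatosic-abdomen types from the component labels."""
    if criterion2 == PP and antpr_band == ABOVE:
        type_a = STEATOSIC
    elif criterion2 == FTP and antpr_band == BELOW:
        type_a = NON_STEATOSIC
    else:
        type_a = INDETERMINATE
    if criterion1 == FP and infpr_band == ABOVE:
        type_b = STEATOSIC
    elif criterion1 == RP and infpr_band == BELOW:
        type_b = NON_STEATOSIC
    else:
        type_b = INDETERMINATE
    return type_a, type_b


def classify_profile(
    metrics: ProfileMetrics,
    th: ClassificationThresholds | None = None,
    mode: str = "strict",
) -> ProfileClassification:
    """Full classification of one metrics vector."""
    th = th or ClassificationThresholds()
    if mode not in ("strict", "nearest"):
        raise DomainError(f"unknown classification mode {mode!r}")
    c1 = classify_criterion1(metrics.k2, metrics.inf_arc, th, mode)
    c2 = classify_criterion2(metrics.k1, max(metrics.area2, 0.0), th, mode)
    ant_band, inf_band = classify_criterion3(metrics.ant_pr, metrics.inf_pr, th)
    type_a, type_b = steatosis_types(c1, c2, ant_band, inf_band)
    return ProfileClassification(c1, c2, ant_band, inf_band, type_a, type_b)
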