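"""Shared test helpers: independent scoring oracle, random valid metrics,
and a hypothesis strategy for valid KeyMetrics."""

from __future__ import annotations

import numpy as np
from hypothesis import strategies as st

from cardioage import KeyMetrics, ScoringConfig
from cardioage.report_parsing import CADRADS_CATEGORIES


def oracle_total(m: KeyMetrics, cfg: ScoringConfig) -> float:
    """Independent brute-force evaluation of the published rule list,
    coded separately from the package's composition path."""
    total = cfg.cac_base_intercept + cfg.cac_slope * m.cac_au
    category_points = {
        "0": 0.0,
        "1": 0.0,
        "2": cfg.increment_cadrads2,
        "3": cfg.increment_cadrads3,
        "4a": cfg.increment_cadrads4a,
        "4b": cfg.increment_cadrads4b,
        "5": cfg.increment_cadrads5,
    }
    total += category_points[m.cadrads]
    if {"LAD", "RCA", "CX"} <= set(m.vessel_over50):
        total += cfg.increment_multivessel
    if m.proximal_lad_over70:
        total += cfg.increment_proximal_lad
    if m.soft_plaque_rca_cx_only:
        total += cfg.increment_soft_plaque_rca_cx
    impaired = m.lvef_percent < cfg.lvef_threshold
    if m.edv_ml is not None and m.edv_ml > cfg.edv_elevated_threshold:
        impaired = True
    if m.esv_ml is not None and m.esv_ml > cfg.esv_elevated_threshold:
        impaired = True
    if impaired:
        total += cfg.increment_low_lvef_or_elevated_volumes
    if m.extracoronary_findings:
        total += cfg.increment_extracoronary
    return total


def random_metrics(rng: np.random.Generator) -> KeyMetrics:
    """One random valid KeyMetrics with renderable precision (CAC one
    decimal, LVEF tenths, integer volumes)."""
    cadrads = str(rng.choice(CADRADS_CATEGORIES))
    cac = round(float(rng.uniform(0, 3000) if rng.random() < 0.9 else rng.uniform(0, 24328)), 1)
    if rng.random() < 0.15:
        cac = 0.0
    lvef = round(float(rng.integers(150, 951)) / 10, 1)
    vessels = set(
        v for v in ("LAD", "RCA", "CX") if rng.random() < 0.35
    )
    proximal = bool(rng.random() < 0.2) and "LAD" in vessels
    if cadrads in ("4a", "4b", "5") and not vessels and not proximal:
        vessels = {"LAD"}
    soft = bool(rng.random() < 0.25) and "LAD" not in vessels
    hrp = bool(rng.random() < 0.3)
    if rng.random() < 0.2:
        edv = esv = None
    else:
        edv = float(rng.integers(70, 301))
        esv = float(rng.integers(15, int(edv) - 10))
    extras = frozenset(
        c
        for c in ("aortic_ectasia", "aortic_aneurysm", "other")
        if rng.random() < 0.1
    )
    return KeyMetrics(
        cac_au=cac,
        cadrads=cadrads,
        lvef_percent=lvef,
        vessel_over50=frozenset(vessels),
        proximal_lad_over70=proximal,
        soft_plaque_rca_cx_only=soft,
        hrp_present=hrp,
        edv_ml=edv,
        esv_ml=esv,
        extracoronary_findings=extras,
    ).validate()


@st.composite
def valid_metrics(draw) -> KeyMetrics:
    cadrads = draw(st.sampled_from(CADRADS_CATEGORIES))
    cac = draw(st.integers(0, 243_280)) / 10
    lvef = draw(st.integers(150, 950)) / 10
    vessels = set(draw(st.sets(st.sampled_from(["LAD", "RCA", "CX"]))))
    proximal = draw(st.booleans()) and "LAD" in vessels
    if cadrads in ("4a", "4b", "5") and not vessels:
        vessels = {"LAD"}
    soft = draw(st.booleans()) and "LAD" not in vessels
    hrp = draw(st.booleans())
    if draw(st.booleans()):
        edv = float(draw(st.integers(70, 300)))
        esv = float(draw(st.integers(15, int(edv) - 11)))
    else:
        edv = esv = None
    extras = frozenset(
        draw(st.sets(st.sampled_from(["aortic_ectasia", "aortic_aneurysm", "other"])))
    )
    return KeyMetrics(
        cac_au=cac,
        cadrads=cadrads,
        lvef_percent=lvef,
        vessel_over50=frozenset(vessels),
        proximal_lad_over70=proximal,
        soft_plaque_rca_cx_only=soft,
        hrp_present=hrp,
        edv_ml=edv,
        esv_ml=esv,
        extracoronary_findings=extras,
    ).validate()
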