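"""Independent brute-force Koppen-Geiger evaluator, for validation only.

This module re-derives the 14-category classification as a flat truth
table: every category is written as one complete boolean conjunction over
the raw monthly values (precedence conditions folded in explicitly), all
14 predicates are evaluated, and exactly one may fire.  It deliberately
shares no code with :mod:`phyloclim.koppen`; agreement between the two on
random climates is part of the validation suite.
"""

from __future__ import annotations


def classify_reference(t_mon, p_mon, hemisphere: str) -> str:
    t = [float(x) for x in t_mon]
    p = [float(x) for x in p_mon]
    assert len(t) == 12 and len(p) == 12
    if hemisphere == "N":
        summer = [3, 4, 5, 6, 7, 8]
    else:
        summer = [9, 10, 11, 0, 1, 2]
    winter = [m for m in range(12) if m not in summer]

    p_ann = sum(p)
    t_ann = sum(t) / 12.0
    p_min, p_max = min(p), max(p)
    p_s = [p[m] for m in summer]
    p_w = [p[m] for m in winter]
    p_smin, p_smax = min(p_s), max(p_s)
    p_wmin, p_wmax = min(p_w), max(p_w)
    t_min, t_max = min(t), max(t)
    warm = sum(1 for x in t if x >= 10.0)

    # dryness threshold (Kottek): depends on where the rain falls
    wfrac = (sum(p_w) / p_ann) if p_ann > 0 else 0.5
    if wfrac >= 2.0 / 3.0:
        p_th = 2.0 * t_ann
    elif wfrac <= 1.0 / 3.0:
        p_th = 2.0 * t_ann + 28.0
    else:
        p_th = 2.0 * t_ann + 14.0

    # driest month of the year falls in the summer half-year
    driest_month = min(range(12), key=lambda m: (p[m], m))
    driest_in_summer = driest_month in summer

    is_b = p_ann < 10.0 * p_th
    is_bw = is_b and p_ann <= 5.0 * p_th
    is_bs = is_b and p_ann > 5.0 * p_th
    hot = t_ann >= 18.0

    is_a = (not is_b) and t_min >= 18.0
    is_af = is_a and p_min >= 60.0
    is_am = is_a and p_min < 60.0 and p_ann >= 25.0 * (100.0 - p_min)
    is_as = (
        is_a and p_min < 60.0 and p_ann < 25.0 * (100.0 - p_min)
        and driest_in_summer
    )
    is_aw = (
        is_a and p_min < 60.0 and p_ann < 25.0 * (100.0 - p_min)
        and not driest_in_summer
    )

    is_c = (not is_b) and (-3.0 < t_min < 18.0)
    cs = is_c and p_smin < p_wmin and p_wmax > 3.0 * p_smin and p_smin < 40.0
    cw = is_c and (not cs) and p_wmin < p_smin and p_smax > 10.0 * p_wmin
    cf = is_c and not cs and not cw
    suff_a = t_max >= 22.0
    suff_b = (not suff_a) and warm >= 4

    table = {
        "Af": is_af,
        "Am": is_am,
        "As": is_as,
        "Aw": is_aw,
        "Bwh": is_bw and hot,
        "Bwk": is_bw and not hot,
        "Bsh": is_bs and hot,
        "Bsk": is_bs and not hot,
        "Csa": cs and suff_a,
        "Csb": cs and suff_b,
        "Cwa": cw and suff_a,
        "Cwb": cw and suff_b,
        "Cfa": cf and suff_a,
        "Cfb": cf and suff_b,
    }
    hits = [cat for cat, ok in table.items() if ok]
    if len(hits) > 1:
        raise AssertionError(f"non-exclusive categories: {hits}")
    return hits[0] if hits else "UNCLASSIFIED"
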