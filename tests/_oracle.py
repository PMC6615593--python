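"""Independent brute-force re-evaluation of the nine flags.

Written directly from the nine-rule list over plain dicts and loops, sharing
no panel machinery with the implementation; used to cross-check the
vectorised flag engine on small random panels.
"""

from __future__ import annotations

import math


def _num(x):
    """None for missing (None/NaN), float otherwise."""
    if x is None:
        return None
    try:
        if math.isnan(float(x)):
            return None
    except (TypeError, ValueError):
        return None
    return float(x)


def brute_force_flags(reports, reference, decisions, thresholds=None):
    """Evaluate all nine flags cell by cell.

    Parameters are plain record lists (dicts); returns
    ``{(country, year): {flag_id: (evaluable, fired)}}`` over every cell
    included for at least one vaccine.
    """
    th = {"denom": 10.0, "cov": 10.0, "ref": 10.0, "cap": 100.0}
    if thresholds is not None:
        th.update(thresholds)

    inc = {}  # (country, year, vaccine) -> included
    for d in decisions:
        inc[(d["country_code"], d["year"], d["vaccine"])] = bool(d["included"])

    rep = {}  # (country, year, vaccine) -> (doses, target)
    for r in reports:
        key = (r["country_code"], r["year"], r["vaccine"])
        rep[key] = (_num(r["doses_administered"]), _num(r["target_population"]))

    ref = {}
    for r in reference:
        ref[(r["country_code"], r["year"])] = (
            _num(r["live_births"]), _num(r["surviving_infants"])
        )

    def target(c, y, vaccine):
        """Reported target if the event is eligible, else None."""
        gate = "DTP3" if vaccine == "DTP1" else vaccine
        if not inc.get((c, y, gate), False):
            return None
        return rep.get((c, y, vaccine), (None, None))[1]

    def cov(c, y, vaccine):
        if not inc.get((c, y, vaccine), False):
            return None
        doses, tgt = rep.get((c, y, vaccine), (None, None))
        if doses is None or tgt is None:
            return None
        return 100.0 * doses / tgt

    def yoy(now, before):
        if now is None or before is None:
            return None
        return 100.0 * (now / before - 1.0)

    cells = sorted({(c, y) for (c, y, v), included in inc.items() if included})
    out = {}
    for c, y in cells:
        lb = target(c, y, "BCG")
        si = target(c, y, "DTP3")
        dtp1 = target(c, y, "DTP1")
        flags = {}

        flags["F1_LB_MISSING"] = (inc.get((c, y, "BCG"), False),
                                  inc.get((c, y, "BCG"), False) and lb is None)
        flags["F2_SI_MISSING"] = (inc.get((c, y, "DTP3"), False),
                                  inc.get((c, y, "DTP3"), False) and si is None)

        comps = [yoy(lb, target(c, y - 1, "BCG")), yoy(si, target(c, y - 1, "DTP3"))]
        comps = [v for v in comps if v is not None]
        flags["F3_YOY_DENOM_GT10"] = (
            bool(comps), any(abs(v) > th["denom"] for v in comps))

        ccomps = [yoy(cov(c, y, "BCG"), cov(c, y - 1, "BCG")),
                  yoy(cov(c, y, "DTP3"), cov(c, y - 1, "DTP3"))]
        ccomps = [v for v in ccomps if v is not None]
        flags["F4_YOY_COV_GT10"] = (
            bool(ccomps), any(abs(v) > th["cov"] for v in ccomps))

        covs = [v for v in (cov(c, y, "BCG"), cov(c, y, "DTP3")) if v is not None]
        flags["F5_COV_GT100"] = (bool(covs), any(v > th["cap"] for v in covs))

        imr = None if (lb is None or si is None) else 1000.0 * (lb - si) / lb
        flags["F6_NEG_IMR"] = (imr is not None, imr is not None and imr < 0)

        ref_lb, ref_si = ref.get((c, y), (None, None))
        d_lb = (None if (lb is None or ref_lb is None)
                else 100.0 * (lb - ref_lb) / ref_lb)
        flags["F7_LB_REF_DIFF_GT10"] = (
            d_lb is not None, d_lb is not None and abs(d_lb) > th["ref"])
        d_si = (None if (si is None or ref_si is None)
                else 100.0 * (si - ref_si) / ref_si)
        flags["F8_SI_REF_DIFF_GT10"] = (
            d_si is not None, d_si is not None and abs(d_si) > th["ref"])

        both = si is not None and dtp1 is not None
        flags["F9_DTP3_NE_DTP1"] = (both, both and si != dtp1)

        out[(c, y)] = flags
    return out
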