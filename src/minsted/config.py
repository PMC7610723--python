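"""YAML configuration loading.

A config file may contain any of the blocks

    optics:    {lambda_sted_nm: 775, numerical_aperture: 1.4, I_s: 1.0}
    localizer: {alpha: 0.15, gamma: 0.97, ratio_Rd: 0.5, d0_nm: 276.8,
                d_min_nm: 40, R_min_nm: 20, I_max: .inf, N_max: 100000}
    scene:     {layout: ring|uniform|explicit, positions: [[x, y], ...],
                n_emitters: 8, ring_radius_nm: 50, field_size_nm: 500,
                sbr: 20, budget_mean: 1000, sigma0_nm: 60}
    sweep:     {varied: {...}, fixed: {...}, replicates: 500, seed: 1}

Missing blocks and keys fall back to the package defaults.
"""

from __future__ import annotations

import math

import yaml

from .experiments import SweepSpec
from .localizer import LocalizerParams
from .psf import EPSFModel
from .simulate import EmitterLayout


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> dict:
    out = {"raw": raw}
    opt = raw.get("optics", {}) or {}
    model = EPSFModel(
        lambda_sted=float(opt.get("lambda_sted_nm", 775.0)),
        numerical_aperture=float(opt.get("numerical_aperture", 1.4)),
        I_s=float(opt.get("I_s", 1.0)),
        d0_override=opt.get("d0_override_nm"),
    )
    out["model"] = model
    loc = raw.get("localizer", {}) or {}
    out["params"] = LocalizerParams(
        alpha=float(loc.get("alpha", 0.15)),
        gamma=float(loc.get("gamma", 0.97)),
        ratio_Rd=float(loc.get("ratio_Rd", 0.5)),
        d0=float(loc.get("d0_nm", model.d0)),
        d_min=float(loc.get("d_min_nm", 40.0)),
        R_min=loc.get("R_min_nm"),
        I_max=float(loc.get("I_max", math.inf)),
        N_max=int(loc.get("N_max", 100_000)),
        precision_kappa=float(loc.get("precision_kappa", 0.58)),
    )
    sc = raw.get("scene", {}) or {}
    if sc:
        out["layout"] = EmitterLayout(
            kind=sc.get("layout", "explicit"),
            positions=tuple(tuple(p) for p in sc.get("positions", ())),
            n_emitters=int(sc.get("n_emitters", 0)),
            field_size=float(sc.get("field_size_nm", 500.0)),
            ring_radius=float(sc.get("ring_radius_nm", 50.0)),
            center=tuple(sc.get("center_nm", (0.0, 0.0))),
            sbr=float(sc.get("sbr", 20.0)),
            budget_mean=float(sc.get("budget_mean", 1000.0)),
            sigma0=float(sc.get("sigma0_nm", 60.0)),
        )
        out["n_detections"] = sc.get("n_detections")
    sw = raw.get("sweep", {}) or {}
    if sw:
        out["sweep"] = SweepSpec(
            varied=sw.get("varied", {}),
            fixed=sw.get("fixed", {}),
            replicates=int(sw.get("replicates", 500)),
            seed=int(sw.get("seed", 1)),
            metrics=tuple(sw.get("metrics", ("sigma",))),
        )
        out["sweep_kind"] = sw.get("kind", "precision_vs_N")
    return out
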