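#!/usr/bin/env python
"""Phantom cohort study: localization sensitivity, null calibration, and
the focus-vs-propagation criterion split.

Three experiments on synthetic cohorts, results to results/phantom_study.json:

1. strong-effect cohort (30% hyperperfusion, 5% noise, n=20): per-criterion
   epileptogenic-zone concordance;
2. focus-free phantoms: fraction of in-brain voxels with |z| > 2, which
   should sit at the Gaussian exceedance 4.55%;
3. propagation cohort (large contralateral low-amplitude blob): the
   largest-cluster criterion should lose sensitivity relative to the
   highest-intensity criterion.
"""

import json
from pathlib import Path

import numpy as np

from siscom.localization import CRITERIA, EZReference
from siscom.pipeline import SiscomConfig, run_siscom
from siscom.synthetic_data import PhantomSpec, make_cohort, make_phantom_pair

RESULTS = Path(__file__).resolve().parents[1] / "results"


def criterion_sensitivities(cohort) -> dict:
    hits = {c: 0 for c in CRITERIA}
    n = 0
    for spec, ictal, interictal, truth in cohort:
        res = run_siscom(
            ictal,
            interictal,
            ez=EZReference(mask=truth.ez_mask, side=truth.ez_side),
            config=SiscomConfig(register=False),
        )
        n += 1
        for c in CRITERIA:
            lab = res.labels[c]
            hits[c] += bool(lab is not None and lab.value.value == "C")
    return {c: round(100.0 * hits[c] / n, 1) for c in CRITERIA}


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    _, cohort = make_cohort(20, amplitudes_pct=[30.0], noises_pct=[5.0], seed=1234)
    out["strong_effect_sensitivity_pct"] = criterion_sensitivities(cohort)

    fracs = []
    for s in range(8):
        spec = PhantomSpec(focus_amplitude_pct=0.0, seed=5000 + s)
        ictal, interictal, _ = make_phantom_pair(spec)
        res = run_siscom(
            ictal, interictal, config=SiscomConfig(register=False, mode="two-sided")
        )
        fracs.append(res.significance.n_significant / res.brain_mask.n_voxels)
    out["null_exceedance_pct"] = {
        "mean": round(100 * float(np.mean(fracs)), 3),
        "gaussian_expectation": 4.55,
        "n_phantoms": len(fracs),
    }

    prop_base = PhantomSpec(
        focus_radius_mm=10.0,
        focus_amplitude_pct=35.0,
        propagation=[((40.0, 15.0, 0.0), 18.0, 15.0)],
    )
    _, prop_cohort = make_cohort(
        12, amplitudes_pct=[35.0], noises_pct=[3.0], seed=55, base_spec=prop_base
    )
    out["propagation_regime_sensitivity_pct"] = criterion_sensitivities(prop_cohort)

    (RESULTS / "phantom_study.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))
    s = out["strong_effect_sensitivity_pct"]
    p = out["propagation_regime_sensitivity_pct"]
    print(f"\nstrong effect: largest-cluster sensitivity {s['cluster1']}%")
    print(
        "propagation regime: highest-intensity "
        f"{p['highest_intensity']}% vs largest-cluster {p['cluster1']}% "
        "(volume criterion misled by the propagation blob)"
    )


if __name__ == "__main__":
    main()
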