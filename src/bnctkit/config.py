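"""Beam/tissue dose-configuration loading.

A dose configuration is a JSON document describing one or more treatment
arms, each with a beam exposure, per-tissue compositions and biological
weights::

    {
      "arms": [
        {
          "name": "BPA-BNCT",
          "beam": {"thermal_fluence": 1.2e12, "d_h": 0.15, "d_gamma": 0.45},
          "weights": {"rbe_n": 3.0, "rbe_h": 3.0},
          "ced": {"contribution_fraction": 0.268},
          "tissue": {
            "tumor": {"nitrogen_pct": 3.5, "boron_conc": 20.6, "cbe": 3.8},
            "brain": {"nitrogen_pct": 2.2, "boron_conc": 5.5, "cbe": 1.35}
          }
        }
      ]
    }

A document without the ``"arms"`` list is read as a single arm.  Per-tissue
``"cbe"`` overrides a scalar ``weights.cbe``; ``"cbe": null`` marks a CBE
that is not estimable.  ``"ced": true`` on a tissue applies the CED
effective-boron fraction to that tissue; ``"depth_correction"`` is an
optional per-tissue multiplicative factor.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

from .dosimetry import BeamExposure, CEDParams, DoseArm, TissueComposition, TissueSpec

__all__ = ["load_dose_config", "parse_dose_config"]


def _parse_arm(doc: dict, default_name: str = "arm") -> DoseArm:
    try:
        beam_doc = doc["beam"]
        tissue_doc = doc["tissue"]
    except KeyError as exc:
        raise ValueError(f"dose config arm is missing key {exc.args[0]!r}") from None
    weights_doc = doc.get("weights", {})
    exposure = BeamExposure(
        thermal_fluence=float(beam_doc["thermal_fluence"]),
        hydrogen_dose=float(beam_doc.get("d_h", 0.0)),
        gamma_dose=float(beam_doc.get("d_gamma", 0.0)),
    )
    scalar_cbe = weights_doc.get("cbe")
    tissues = {}
    ced_tissues = []
    for name, spec in tissue_doc.items():
        cbe = spec.get("cbe", scalar_cbe)
        tissues[name] = TissueSpec(
            composition=TissueComposition(
                nitrogen_pct=float(spec["nitrogen_pct"]),
                boron_conc=float(spec.get("boron_conc", 0.0)),
            ),
            cbe=None if cbe is None else float(cbe),
            depth_correction=float(spec.get("depth_correction", 1.0)),
        )
        if spec.get("ced", False):
            ced_tissues.append(name)
    ced_doc = doc.get("ced")
    ced = None if ced_doc is None else CEDParams(float(ced_doc["contribution_fraction"]))
    if ced_tissues and ced is None:
        raise ValueError("tissues flagged 'ced' but no ced.contribution_fraction given")
    return DoseArm(
        name=doc.get("name", default_name),
        exposure=exposure,
        tissues=tissues,
        rbe_n=float(weights_doc.get("rbe_n", 1.0)),
        rbe_h=float(weights_doc.get("rbe_h", 1.0)),
        ced=ced,
        ced_tissues=tuple(ced_tissues),
    )


def parse_dose_config(doc: dict) -> List[DoseArm]:
    """Parse an already-loaded JSON document into dose arms."""
    if "arms" in doc:
        arms = [_parse_arm(a, default_name=f"arm{i+1}") for i, a in enumerate(doc["arms"])]
    else:
        arms = [_parse_arm(doc)]
    if not arms:
        raise ValueError("dose config defines no arms")
    return arms


def load_dose_config(path: Union[str, Path]) -> List[DoseArm]:
    """Load a beam/tissue JSON configuration into a list of dose arms."""
    return parse_dose_config(json.loads(Path(path).read_text()))
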