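#!/usr/bin/env python
"""Check the per-beat feature identities and the Katz FD properties.

Writes results/feature_checks.json: worst identity violations over 1,000
random pulses, the ramp FD, and the monotone high-frequency response.
"""

import argparse
import json
from pathlib import Path

from hemotrace import experiments as ex

OUT = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    errs = ex.feature_identity_study(n_beats=1000, seed=args.seed)
    kz = ex.katz_study(n_seeds=100)
    out = {"identity_max_errors": errs, "katz": kz}
    (OUT / "feature_checks.json").write_text(json.dumps(out, indent=2))
    print("worst identity violations over 1000 random beats:")
    for name, err in errs.items():
        print(f"  {name}: {err:.2e}")
    print(f"ramp FD = {kz['ramp_fd']:.12f}; "
          f"FD rose under 10% high-frequency admixture in "
          f"{100 * kz['monotone_fraction']:.0f}/100 cases")


if __name__ == "__main__":
    main()
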