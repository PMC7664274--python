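"""Liquid junction potentials for the study's printed solution pairs.

Evaluates the Henderson equation on the dissociated recipes: the
K-gluconate current-clamp internal against ACSF, and the CsCl
sodium-channel internal against both the reduced-sodium external and
ACSF (nucleated-patch configuration).  Writes results/ljp.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ephysepi.solutions import (
    ACSF_BATH, CSCL_NA_INTERNAL, KGLUCONATE_INTERNAL, NA30_EXTERNAL,
    henderson_ljp,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    pairs = [
        ("K-gluconate internal", "ACSF", KGLUCONATE_INTERNAL, ACSF_BATH),
        ("CsCl Na-channel internal", "30 mM Na external",
         CSCL_NA_INTERNAL, NA30_EXTERNAL),
        ("CsCl Na-channel internal", "ACSF", CSCL_NA_INTERNAL, ACSF_BATH),
    ]
    rows = [{"pipette": p, "bath": b,
             "ljp_mv": round(henderson_ljp(ip, ep), 2)}
            for p, b, ip, ep in pairs]
    out = Path(args.out)
    out.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(out / "ljp.csv", index=False)
    print(df.to_string(index=False))
    print("\nRecorded voltages are corrected offline by subtracting the "
          "pipette/bath LJP (e.g. a -80 mV reading under K-gluconate/ACSF "
          "is a true -94.3 mV).")


if __name__ == "__main__":
    main()
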