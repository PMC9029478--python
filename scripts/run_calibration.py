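"""Regenerate the committed CONT/MCT parameter defaults.

Runs the deterministic, noise-free calibration pass against the reference
endpoint table and prints the resulting parameter values in the form used
in ``atriomech/params.py``.  Run from the repository root:

    python scripts/run_calibration.py
"""

import sys

from atriomech.calibrate import calibrate_defaults

FIELDS = ("tau_ca_rise", "tau_ca_decay", "k_act", "k_rel", "hill_n",
          "f_ref", "sfr_gain_ca", "sfr_gain_sens", "prp_load_gain")


def main():
    cont, mct, report = calibrate_defaults()
    for label, p in (("CONT", cont), ("MCT", mct)):
        print(f"\n{label}_DEFAULTS = MuscleParams(")
        print(f'    group_label="{label}",')
        print(f"    diameter={p.diameter},")
        for f in FIELDS:
            print(f"    {f}={getattr(p, f):.6f},")
        print(")")
    print("\n# calibration report (achieved vs target):")
    for name in report.targets:
        print(f"#  {name}: target {report.targets[name]:.4f} "
              f"achieved {report.achieved[name]:.4f}")
    for note in report.notes:
        print(f"#  note: {note}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
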