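"""Per-subject RTOP gradient fields and group directional statistics.

For each synthetic subject, computes the finite-element surface gradient of
the planted RTOP field, extracts per-subdivision main directions, and
summarizes the population with spherical mean, dispersion, bootstrap CI,
and the Rayleigh uniformity test (df = 3); also extracts isocontours of one
subject's field.
"""

import argparse
import json

from rtopmap.workflow import PipelineConfig, run_stage

if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/pipeline")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    report = run_stage("gradients", PipelineConfig(out_dir=args.out,
                                                   seed=args.seed))
    print(f"group mean gradient direction recovered within "
          f"{report['max_direction_error_deg']:.1f} degrees of the planted "
          f"axis across all subdivisions (N = {report['n_subjects']}); "
          f"largest Rayleigh p = {report['max_rayleigh_p']:.1e}.")
    print(json.dumps(report, indent=2))
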