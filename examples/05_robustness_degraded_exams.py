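"""Soft-failure behaviour on degraded and incomplete exams.

Streak artifacts (dense contrast in a nearby vein) and missing structures
must never crash the chain: each stage records a per-compartment miss and
every downstream compartment is marked undetected, exactly as a per-exam
detection tally expects.
"""

from ctpa_cade.phantom import (ArtifactSpec, PhantomSpec, StreakSpec,
                               generate)
from ctpa_cade.pipeline import run_pipeline

cases = {
    "clean": PhantomSpec(seed=8),
    "streak artifacts": PhantomSpec(
        artifacts=ArtifactSpec(streak=StreakSpec(amplitude_hu=350.0)),
        noise_sd_hu=30.0, seed=8),
    "no trachea": PhantomSpec(trachea=None, seed=8),
    "no aorta": PhantomSpec(aorta=None, seed=8),
}

stages = ("trachea", "carina", "dao", "aao", "pt")
print(f"{'case':<18}" + "".join(f"{s:>9}" for s in stages) + "  failures")
for name, spec in cases.items():
    result = run_pipeline(generate(spec).volume)
    flags = "".join(f"{str(result.landmarks.detected[s]):>9}" for s in stages)
    fails = "; ".join(f"{k}:{v}" for k, v in
                      result.report.failure_stages.items()) or "-"
    print(f"{name:<18}{flags}  {fails}")

# Failure is monotone along the chain: once a prerequisite stage misses, no
# downstream compartment is ever reported as detected, and the failure stage
# records where the chain broke ('upstream:...' for inherited misses).
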