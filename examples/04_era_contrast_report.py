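"""Full era-stratified analysis: did detection improve between eras?

Generates the package's reference two-era surveillance study (detection of
single-case outbreaks improves from 20% to 50% in the second era), runs the
complete report, and prints the era contrast in the annual small-outbreak
deficit.
"""

import tempfile
from pathlib import Path

from outbreaklaw import RunConfig, run_full_analysis
from outbreaklaw.simulate import default_config, generate, write_dataset

records, truth = generate(default_config(seed=7))
tmp = Path(tempfile.mkdtemp())
write_dataset(records, truth, tmp / "surveillance.csv", tmp / "truth.json")

report = run_full_analysis(
    RunConfig(
        input_path=str(tmp / "surveillance.csv"),
        out_dir=str(tmp / "report"),
        n_boot_gof=100,
        n_boot_cri=200,
        seed=5,
    )
)

for key, period in report["periods"].items():
    pl = period["power_law"]
    print(
        f"{key}: n={period['n_outbreaks']}, xmin={pl['point']['xmin']}, "
        f"alpha={pl['point']['alpha']:.3f}, "
        f"small deficit {pl['deficits_point']['small_outbreak_deficit_annual']:.0f}/yr"
    )

contrast = report["era_contrast"]
print(
    f"\nannual small-outbreak deficit: {contrast['annual_small_deficit_era1']:.0f}/yr "
    f"-> {contrast['annual_small_deficit_era2']:.0f}/yr "
    f"({contrast['percent_change_point']:.0f}% decrease)"
)
print(f"report bundle written under {tmp / 'report'}")
# A shrinking deficit between eras indicates improved outbreak detection —
# the package's measure of a surveillance intervention's effect.
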