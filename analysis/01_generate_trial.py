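"""Generate the virtual PK trial used by the downstream analyses.

Emulates the two-arm continuous-infusion study: 16 subjects on 2 g LD +
1 g/8 h and 15 on 2 g LD + 2 g/8 h, day-3 plasma sampling (pre-infusion and
1.5, 3, 6, 8 h) plus one BAL-derived ELF sample at 6 h, 15% assay noise,
log-uniform BAL dilution, and LOQ censoring.  Writes dosing/observation/BAL
tables and the ground truth to results/trial/.
"""

from pathlib import Path

from meropk.synthetic_trial import TrialDesign, generate_trial

OUT = Path(__file__).resolve().parents[1] / "results" / "trial"
SEED = 1


def main() -> None:
    design = TrialDesign(seed=SEED)
    trial = generate_trial(design)
    trial.write(OUT)
    obs = trial.observations
    n_bloq = int(obs["bloq"].sum())
    print(f"wrote virtual trial to {OUT}")
    print(f"  subjects: {len(trial.truth)} (arms: {design.n_per_arm})")
    print(f"  observations: {len(obs)} ({(obs['analyte']=='plasma').sum()} plasma, "
          f"{(obs['analyte']=='elf').sum()} ELF; {n_bloq} below LOQ)")
    print(f"  true median CL: {trial.truth['CL'].median():.2f} L/h")


if __name__ == "__main__":
    main()
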