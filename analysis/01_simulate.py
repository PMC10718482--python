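"""Generate the study-frame cohort: 47 participants, 7 days from a Monday.

Writes device-dialect export files, participant attributes and ground truth
under results/cohort/, and prints the person-day bookkeeping.
"""

from pathlib import Path

from actipat import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 7


def main() -> None:
    cfg = syn.study_frame_config(seed=SEED)
    truth = syn.generate_cohort(cfg, OUT)
    n_weekday = sum(1 for (_, d) in truth.bins if d.weekday() < 5)
    print(f"cohort: {len(truth.participants)} participants x {cfg.n_days} days")
    print(
        f"person-days: {truth.person_days} "
        f"({n_weekday} weekday / {truth.person_days - n_weekday} weekend)"
    )
    print(f"groups: {truth.participants['group'].value_counts().to_dict()}")
    print(f"exports written to {OUT}")


if __name__ == "__main__":
    main()
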