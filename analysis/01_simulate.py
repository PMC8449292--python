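"""Generate the default synthetic study: lexicon, cohort, admission notes, truth.

Emulates a three-group psychiatric admission cohort (612 depression / 83
schizophrenia / 37 bipolar admissions over 571 patients) with group-specific
RDoC term probabilities and a logistic long-stay outcome planted on negative
valence (OR 1.06 per point) and arousal (OR 0.95 per point).

Bulk artifacts (notes corpus, cohort) go to scratch/sim; they are
regenerated, not shipped.
"""

from pathlib import Path

import pandas as pd

from rdocpheno import generate_cohort, generate_lexicon, generate_notes, write_lexicon
from rdocpheno.cohort import write_cohort
from rdocpheno.simulate import GeneratorSpec, write_truth

SEED = 0
OUT = Path("scratch/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = GeneratorSpec(seed=SEED)
    lexicon = generate_lexicon(spec)
    cohort, truth = generate_cohort(spec)
    notes = generate_notes(spec, lexicon, cohort)

    write_lexicon(lexicon, OUT / "lexicon.csv")
    write_cohort(cohort, OUT / "cohort.csv")
    write_truth(truth, OUT / "truth.json")
    pd.DataFrame({"admission_id": [n.admission_id for n in notes],
                  "text": [n.raw_text for n in notes]}).to_csv(OUT / "notes.csv", index=False)

    sizes = cohort.df["diagnosis"].value_counts()
    print(f"simulated {len(cohort)} admissions over {cohort.df['patient_id'].nunique()} patients")
    print(f"group sizes: {sizes.to_dict()}")
    print(f"lexicon: {len(lexicon.domains)} domains x {spec.terms_per_domain} terms")
    print(f"wrote lexicon.csv, cohort.csv, notes.csv, truth.json under {OUT}/")


if __name__ == "__main__":
    main()
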