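"""Score every simulated admission note on the five RDoC domains.

Runs the full text pipeline (translate -> normalize -> tokenize -> match) and
writes the score matrix plus a per-group mean (SD) summary of the fractions
— the computed-phenotype table the group comparisons consume.
"""

from pathlib import Path

import pandas as pd

from rdocpheno import load_lexicon, prepare_document, score_corpus, write_scores
from rdocpheno.text import read_notes_csv

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lexicon = load_lexicon(SIM / "lexicon.csv")
    docs = [prepare_document(d) for d in read_notes_csv(SIM / "notes.csv")]
    vectors = score_corpus(docs, lexicon)
    write_scores(vectors, lexicon, SIM / "scores.csv")

    scores = pd.DataFrame([{"admission_id": v.admission_id, **v.scores} for v in vectors])
    cohort = pd.read_csv(SIM / "cohort.csv", dtype={"admission_id": str})
    merged = scores.merge(cohort[["admission_id", "diagnosis"]], on="admission_id")
    summary = merged.groupby("diagnosis")[list(lexicon.domains)].agg(["mean", "std"]).round(3)
    summary.to_csv(RESULTS / "score_summary.csv")
    print(f"scored {len(vectors)} notes; per-group domain score mean/SD:")
    print(summary.T)


if __name__ == "__main__":
    main()
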