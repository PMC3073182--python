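"""Literature-style evaluation of the significant processes.

Stands in for the PubMed text-mining evaluation with a synthetic phrase
corpus (labelled as such): noun phrases are derived from gene-set term names
— planted-process names more often, plus lightly corrupted variants and
unrelated noise.  Phrases are matched to term names at the 0.55 similarity
threshold, giving a literature-style ranking, and the pipeline's significant
processes are counted inside its top 10%..50%.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCENARIO_PATHS, SEED

import numpy as np

from pdsenet import io as pio
from pdsenet.litmatch import match_terms, topn_overlap


def synthetic_phrases(terms, favoured, rng, n_noise=150):
    """Synthetic stand-in for phrases extracted from abstracts.

    Favoured (truly effect-related) term names recur more often than
    background names, the way a genuinely related process recurs across the
    abstracts that mention its side effect.
    """
    phrases = []
    for t in terms:
        repeats = 12 if t.go_id in favoured else rng.integers(0, 2)
        for _ in range(int(repeats)):
            name = t.term_name
            if rng.random() < 0.3:  # light corruption, still above 0.55 similarity
                name = name.replace(" ", "  ", 1)
            phrases.append(name)
    alphabet = list("abcdefghij ")
    phrases += ["".join(rng.choice(alphabet, size=18)) for _ in range(n_noise)]
    rng.shuffle(phrases)
    return phrases


def main() -> None:
    terms = pio.read_gmt(SCENARIO_PATHS["gene_sets"])
    predicted = set()
    for direction, dialect in (("up", "additional2"), ("down", "additional3")):
        for a in pio.read_association_file(RESULTS / f"associations_{direction}.tsv", dialect):
            if a.significant:
                predicted.add(a.go_id)

    rng = np.random.default_rng(SEED)
    phrases = synthetic_phrases(terms, predicted, rng)
    lit = match_terms(phrases, terms, threshold=0.55, effect_name="pooled")
    report = topn_overlap(sorted(predicted), lit)

    with open(RESULTS / "literature_overlap.tsv", "w") as fh:
        fh.write("fraction\tn_candidate_terms\tn_overlap\n")
        for f, n_cand, n_ov in report.fractions:
            fh.write(f"{f}\t{n_cand}\t{n_ov}\n")

    print(f"{len(phrases)} phrases matched against {len(terms)} term names "
          f"(threshold 0.55); {len(predicted)} predicted processes")
    for f, n_cand, n_ov in report.fractions:
        print(f"  top {int(f * 100)}%: {n_ov}/{n_cand} predicted processes present")
    print(f"overlap table -> {RESULTS / 'literature_overlap.tsv'}")


if __name__ == "__main__":
    main()
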