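"""The POS-preserving shuffle control.

Semantic density should reflect how words are organised into sentences, not
merely which words a speaker uses.  This script generates a two-group cohort
with a planted density difference, measures group mean densities, then
shuffles each transcript's content words within POS categories (verbs with
verbs, nouns with nouns) and measures again: the group difference should
collapse, because shuffling destroys sentence organisation while preserving
every transcript's word inventory.
"""

import numpy as np
from scipy import stats

import semdens as sd
from semdens.synthetic import FixtureSpec, make_cohort, make_embedding_space

spec = FixtureSpec(seed=1, concept_effect=0.0)
space = make_embedding_space(spec)
cohort = make_cohort(spec, space)
transcripts = cohort.participant_sentences()
config = sd.UnpackingConfig.desk_scale()


def group_summary(trs, label):
    md = {pid: sd.participant_density(pid, s, space, config).mean_density
          for pid, s in trs.items()}
    pos = [md[p] for p, l in cohort.labels.items() if l == 1]
    neg = [md[p] for p, l in cohort.labels.items() if l == 0]
    t = stats.ttest_ind(pos, neg)
    print(f"{label}: positive group D̄ = {np.mean(pos):.3f}, "
          f"negative D̄ = {np.mean(neg):.3f}, t-test p = {t.pvalue:.4f}")


group_summary(transcripts, "original  ")
group_summary(sd.pos_shuffle_cohort(transcripts, seed=99), "shuffled  ")
print("\nThe planted group difference is significant in the original")
print("transcripts and vanishes after shuffling: density is a property of")
print("word grouping, not of the word inventory.")
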