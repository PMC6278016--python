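"""Score competing candidate sentences for the Population element.

When several sentences of one abstract are decoded as Population
candidates, each is scored with wTotal = wPoM + wPoT + wCo + wSe:
position (METHOD section or first third), title overlap (f5), P/I
coexistence, and semantic evidence (f1+f2).  The highest total wins.
"""

from picoextract import SentenceRecord, score_sentence
from picoextract.features import FeatureVector

candidates = {"POPULATION", "INTERVENTION"}


def vector(**kw):
    base = dict(f1=0, f2=0, f3=0, f4=0, f5=0, f6=0, f7="NOHEADING",
                f8=12, f9=1, f10=[])
    base.update(kw)
    return FeatureVector(**base)


# A METHOD-section sentence sharing 2 title words, carrying one demographic
# and one disorder hit, decoded as both P and I:
strong = score_sentence(
    "POPULATION",
    SentenceRecord("A", 3, "Patients with diabetes were enrolled.",
                   gold_labels=("POPULATION",)),
    vector(f1=1, f2=1, f5=2, f7="METHOD"),
    candidates, is_structured=True, abstract_len=9,
)
# A CONCLUSION sentence with the same semantic evidence but no positional
# or coexistence support:
weak = score_sentence(
    "POPULATION",
    SentenceRecord("A", 9, "We conclude patients benefit.",
                   gold_labels=("OTHER",)),
    vector(f1=1, f2=1, f7="CONCLUSION"),
    {"POPULATION"}, is_structured=True, abstract_len=9,
)

for name, s in [("METHOD candidate", strong), ("CONCLUSION candidate", weak)]:
    print(f"{name}: wPoM={s.w_pom} wPoT={s.w_pot} wCo={s.w_co} wSe={s.w_se} "
          f"-> total {s.total}")
# The METHOD candidate totals 8 vs 2: position, title overlap and P/I
# coexistence each nudge the choice toward the typical Population sentence
# without letting any single cue dominate.
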