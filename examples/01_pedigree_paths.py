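"""Kinship paths in a small three-generation pedigree.

Builds a pedigree by hand, then enumerates the genealogical connections
(up-through-ancestors, down at most once) between the proband and selected
relatives, with their relationship labels.
"""

from hemeped import Individual, Pedigree, connecting_paths, relationship_label
from hemeped.pedigree import FEMALE, MALE, AFFECTED, UNAFFECTED


def person(iid, sex, father=None, mother=None, affected=False):
    return Individual(
        id=iid, sex=sex, father_id=father, mother_id=mother,
        affected=AFFECTED if affected else UNAFFECTED,
    )


ped = Pedigree(
    [
        person("grandfather", MALE),
        person("grandmother", FEMALE),
        person("father", MALE, "grandfather", "grandmother"),
        person("uncle", MALE, "grandfather", "grandmother", affected=True),
        person("mother", FEMALE),
        person("proband", MALE, "father", "mother", affected=True),
        person("sister", FEMALE, "father", "mother"),
    ]
)

for target in ("grandfather", "uncle", "sister"):
    for path in connecting_paths(ped, "proband", target, max_len=5):
        print(
            f"proband -> {target}: {' - '.join(path.vertices)}  "
            f"[{relationship_label(path)}, {path.ups} up / {path.downs} down]"
        )

# The uncle connects through father and grandparent (one oblique path per
# grandparent), the sister through both parents (the two equally short paths
# that make full siblings line-ambiguous in the segregation analysis).
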