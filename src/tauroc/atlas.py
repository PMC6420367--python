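"""Atlas definitions: integer labels, hemisphere pairs, and region roles.

The default atlas is a synthetic stand-in modeled on an AAL-style labeling
scheme: 46 bilateral gray-matter regions (92 lateralized labels), bilateral
cerebellar crus 1/2 as the SUVR reference region, further cerebellar and
vermis/brainstem labels for a total of 122, and an amyloid meta-ROI covering
bilateral parietal (incl. posterior cingulate and precuneus), orbitofrontal,
prefrontal, temporal, and anterior cingulate cortices.  It carries no real
anatomy — only the label bookkeeping the pipeline needs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

LEFT_SUFFIX = "_L"
RIGHT_SUFFIX = "_R"

#: 46 combined gray-matter region names of the default (stand-in) atlas.
GRAY_MATTER_REGIONS: tuple[str, ...] = (
    "precentral", "frontal_sup", "frontal_sup_orb", "frontal_mid",
    "frontal_mid_orb", "frontal_inf_oper", "frontal_inf_tri", "frontal_inf_orb",
    "rolandic_oper", "supp_motor_area", "olfactory", "frontal_sup_medial",
    "frontal_med_orb", "rectus", "insula_ant", "insula_post",
    "cingulum_ant", "cingulum_mid", "cingulum_post", "hippocampus",
    "parahippocampal", "amygdala", "calcarine", "cuneus",
    "lingual", "occipital_sup", "occipital_mid", "occipital_inf",
    "fusiform", "postcentral", "parietal_sup", "parietal_inf",
    "supramarginal", "angular", "precuneus", "paracentral_lobule",
    "caudate", "putamen", "pallidum", "thalamus",
    "heschl", "temporal_sup", "temporal_pole_sup", "temporal_mid",
    "temporal_pole_mid", "temporal_inf",
)

OCCIPITAL_COMPOSITE_REGIONS: tuple[str, ...] = (
    "occipital_sup", "occipital_mid", "occipital_inf",
)

#: Combined names pooled into the global amyloid meta-ROI.
META_ROI_REGIONS: tuple[str, ...] = (
    "parietal_sup", "parietal_inf", "supramarginal", "angular", "precuneus",
    "cingulum_post", "frontal_sup_orb", "frontal_mid_orb", "frontal_inf_orb",
    "frontal_med_orb", "rectus", "frontal_sup", "frontal_mid",
    "frontal_inf_tri", "frontal_sup_medial", "temporal_sup", "temporal_mid",
    "temporal_inf", "cingulum_ant",
)

_CEREBELLAR_PAIRS: tuple[str, ...] = (
    "cerebelum_crus1", "cerebelum_crus2", "cerebelum_3", "cerebelum_4_5",
    "cerebelum_6", "cerebelum_7b", "cerebelum_8", "cerebelum_9", "cerebelum_10",
)

_UNPAIRED: tuple[str, ...] = (
    "vermis_1_2", "vermis_3", "vermis_4_5", "vermis_6", "vermis_7",
    "vermis_8", "vermis_9", "vermis_10", "midbrain", "pons", "medulla",
    "corpus_callosum",
)

REFERENCE_REGIONS: tuple[str, ...] = ("cerebelum_crus1", "cerebelum_crus2")


@dataclass(frozen=True)
class AtlasDefinition:
    """Label bookkeeping for one atlas.

    ``label_map`` maps every integer label to its lateralized (or unpaired)
    name; ``left_right_pairs`` lists (left label, right label, combined name);
    ``roles`` tags each label as ``gray``, ``reference``, ``meta_roi`` (gray
    regions also in the amyloid composite) or ``other``.
    """

    label_map: dict[int, str]
    left_right_pairs: tuple[tuple[int, int, str], ...]
    reference_labels: tuple[int, ...]
    meta_roi_labels: tuple[int, ...] = ()
    roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for left, right, name in self.left_right_pairs:
            if left in seen or right in seen or left == right:
                raise ValueError(f"left/right pairs are not disjoint at {name!r}")
            seen.update((left, right))
        for lab in self.reference_labels:
            if lab not in self.label_map:
                raise ValueError(f"reference label {lab} missing from label map")
        ref = set(self.reference_labels)
        for left, right, name in self.gray_matter_pairs:
            if left in ref or right in ref:
                raise ValueError(f"reference label reused as gray matter in {name!r}")

    # ------------------------------------------------------------- queries
    @property
    def gray_matter_pairs(self) -> tuple[tuple[int, int, str], ...]:
        ref = set(self.reference_labels)
        return tuple(
            (l, r, name) for (l, r, name) in self.left_right_pairs
            if self.roles.get(l, "gray") in ("gray", "meta_roi") and l not in ref
        )

    @property
    def gray_matter_names(self) -> tuple[str, ...]:
        return tuple(name for (_, _, name) in self.gray_matter_pairs)

    def labels_for(self, combined_name: str) -> tuple[int, ...]:
        for left, right, name in self.left_right_pairs:
            if name == combined_name:
                return (left, right)
        for lab, name in self.label_map.items():
            if name == combined_name:
                return (lab,)
        raise KeyError(f"unknown region {combined_name!r}")

    # ----------------------------------------------------------------- I/O
    def to_json(self, path) -> None:
        """Write the labels.json interchange format."""
        pair_of = {}
        for i, (left, right, name) in enumerate(self.left_right_pairs):
            pair_of[left] = (i, "left", name)
            pair_of[right] = (i, "right", name)
        meta = set(self.meta_roi_labels)
        out = {}
        for lab in sorted(self.label_map):
            pid, hemi, _combined = pair_of.get(lab, (None, None, None))
            role = self.roles.get(lab, "gray")
            if lab in set(self.reference_labels):
                role = "reference"
            elif lab in meta:
                role = "meta_roi"
            out[str(lab)] = {
                "name": self.label_map[lab],
                "hemisphere": hemi,
                "pair_id": pid,
                "role": role,
            }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AtlasDefinition":
        with open(path) as fh:
            raw = json.load(fh)
        label_map = {int(k): v["name"] for k, v in raw.items()}
        roles = {int(k): v["role"] for k, v in raw.items()}
        pairs: dict[int, dict[str, int]] = {}
        combined: dict[int, str] = {}
        for k, v in raw.items():
            if v.get("pair_id") is not None:
                pairs.setdefault(v["pair_id"], {})[v["hemisphere"]] = int(k)
                name = v["name"]
                for suf in (LEFT_SUFFIX, RIGHT_SUFFIX):
                    if name.endswith(suf):
                        name = name[: -len(suf)]
                combined[v["pair_id"]] = name
        pair_list = tuple(
            (pairs[pid]["left"], pairs[pid]["right"], combined[pid])
            for pid in sorted(pairs)
        )
        reference = tuple(sorted(k for k, r in roles.items() if r == "reference"))
        meta = tuple(sorted(k for k, r in roles.items() if r == "meta_roi"))
        return cls(label_map, pair_list, reference, meta, roles)


def default_atlas() -> AtlasDefinition:
    """The 122-label stand-in atlas (46 gray-matter pairs + cerebellum/vermis)."""
    label_map: dict[int, str] = {}
    pairs: list[tuple[int, int, str]] = []
    roles: dict[int, str] = {}
    nxt = 1
    for name in GRAY_MATTER_REGIONS:
        left, right = nxt, nxt + 1
        label_map[left] = name + LEFT_SUFFIX
        label_map[right] = name + RIGHT_SUFFIX
        roles[left] = roles[right] = "gray"
        pairs.append((left, right, name))
        nxt += 2
    for name in _CEREBELLAR_PAIRS:
        left, right = nxt, nxt + 1
        label_map[left] = name + LEFT_SUFFIX
        label_map[right] = name + RIGHT_SUFFIX
        roles[left] = roles[right] = "reference" if name in REFERENCE_REGIONS else "other"
        pairs.append((left, right, name))
        nxt += 2
    for name in _UNPAIRED:
        label_map[nxt] = name
        roles[nxt] = "other"
        nxt += 1
    reference = tuple(
        lab for (l, r, name) in pairs if name in REFERENCE_REGIONS for lab in (l, r)
    )
    meta = tuple(
        lab for (l, r, name) in pairs if name in META_ROI_REGIONS for lab in (l, r)
    )
    for lab in meta:
        roles[lab] = "meta_roi"
    atlas = AtlasDefinition(label_map, tuple(pairs), reference, meta, roles)
    assert len(atlas.gray_matter_names) == 46
    assert len(label_map) == 122
    return atlas
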