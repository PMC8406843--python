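"""KO catalog construction from compound -> KO membership tables.

A catalog is the union of the KEGG orthologs linked to a requested set of
compounds, retaining per-KO compound membership so the exact compound
combination each KO belongs to can be tabulated, plus (optionally) the
intersection with the KOs annotated in a cohort.
"""

from __future__ import annotations

import importlib.resources
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "KOCatalog",
    "load_compound_map",
    "build_catalog",
    "intersect_annotated",
    "compound_distribution",
    "DEFAULT_COMPOUNDS",
]

_COMPOUND_RE = re.compile(r"^C\d{5}$")
_KO_RE = re.compile(r"^K\d{5}$")

#: The 13 compounds of the packaged map: acetate, butyrate, propionate,
#: pyruvate, acetyl-CoA, butyryl-CoA, lactate, succinate (SCFA class) and
#: isobutyrate, valerate, isovalerate, isocaproate, 2-methylbutyrate (BCFA).
DEFAULT_COMPOUNDS = [
    "C00033", "C00246", "C00163", "C00022", "C00024", "C00136", "C00186",
    "C00042", "C02632", "C00803", "C08262", "C21399", "C18319",
]


@dataclass
class KOCatalog:
    """KO set with per-KO compound membership and an annotated overlap."""

    membership: dict[str, frozenset]
    annotated_overlap: set = field(default_factory=set)

    @property
    def ko_ids(self) -> set:
        return set(self.membership)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "ko_id": ko,
                "compounds": ",".join(sorted(comps)),
                "annotated": ko in self.annotated_overlap,
            }
            for ko, comps in sorted(self.membership.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_compound_map(path=None) -> pd.DataFrame:
    """Load a compound->KO map TSV (columns compound_id, ko_id[, class]).

    With no path, the packaged 13-compound map is used.  Accession formats
    are validated (C#####/K#####).
    """
    if path is None:
        ref = importlib.resources.files("scfamet.data") / "compound_ko_map.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("compound_id", "ko_id"):
        if col not in df.columns:
            raise ValueError(f"compound map missing column {col!r}")
    bad_c = [c for c in df["compound_id"].unique() if not _COMPOUND_RE.match(str(c))]
    bad_k = [k for k in df["ko_id"].unique() if not _KO_RE.match(str(k))]
    if bad_c or bad_k:
        raise ValueError(f"malformed accessions: {bad_c + bad_k}")
    return df


def build_catalog(cmap: pd.DataFrame, compounds: list[str]) -> KOCatalog:
    """Union the KOs of the requested compounds into a catalog.

    Compounds absent from the map are skipped with a warning; an empty
    union is an error.
    """
    if not compounds:
        raise ValueError("compounds must be non-empty")
    available = set(cmap["compound_id"])
    membership: dict[str, set] = {}
    for comp in compounds:
        if comp not in available:
            warnings.warn(f"compound {comp} absent from map; skipped", stacklevel=2)
            continue
        for ko in cmap.loc[cmap["compound_id"] == comp, "ko_id"]:
            membership.setdefault(ko, set()).add(comp)
    if not membership:
        raise ValueError("no requested compound present in the map: empty KO union")
    return KOCatalog(membership={k: frozenset(v) for k, v in membership.items()})


def intersect_annotated(catalog: KOCatalog, annotated: set) -> KOCatalog:
    """Return a catalog whose annotated_overlap is ko_ids ∩ annotated."""
    if not annotated:
        raise ValueError("annotated KO set must be non-empty")
    overlap = catalog.ko_ids & set(annotated)
    if not overlap:
        warnings.warn("catalog and annotated KO sets are disjoint", stacklevel=2)
    return KOCatalog(membership=dict(catalog.membership), annotated_overlap=overlap)


def compound_distribution(catalog: KOCatalog, ko_subset: set) -> pd.DataFrame:
    """Count KOs per exact compound combination (UpSet-style rows).

    Every KO in ``ko_subset`` contributes to exactly one row, so counts sum
    to ``len(ko_subset)``.
    """
    unknown = set(ko_subset) - catalog.ko_ids
    if unknown:
        raise ValueError(f"KOs not in catalog: {sorted(unknown)}")
    combos: dict[tuple, int] = {}
    for ko in ko_subset:
        key = tuple(sorted(catalog.membership[ko]))
        combos[key] = combos.get(key, 0) + 1
    rows = [
        {"compound_combination": "+".join(key), "count": n}
        for key, n in sorted(combos.items())
    ]
    return pd.DataFrame(rows, columns=["compound_combination", "count"])
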