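"""Extrinsic hint sets: build, filter, merge and intersect.

A hint is a located evidence atom — an intron span or a 3-bp start/stop codon
interval — tagged with its source (``rnaseq`` or ``protein``) and a
multiplicity (read or protein support count).  Hint identity is exact:
(seq_id, kind, start, end, strand), with no fuzz window, since both hint
producers emit exact splice coordinates.  A HintSet holds at most one record
per (key, source); merging records from both sources keeps them separately
tagged, while intersection takes the pairwise minimum multiplicity as the
conservative combined weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genomic_model import GenomicInterval, introns_of

HINT_KINDS = ("intron", "start", "stop")
_SRC_CODE = {"rnaseq": "E", "protein": "P"}
_CODE_SRC = {v: k for k, v in _SRC_CODE.items()}

HintKey = tuple[str, str, int, int, str]  # (seq_id, kind, start, end, strand)


@dataclass(frozen=True)
class Hint:
    kind: str  # intron | start | stop
    location: GenomicInterval
    source: str  # rnaseq | protein
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.kind not in HINT_KINDS:
            raise ValueError(f"unknown hint kind {self.kind!r}")
        if self.source not in _SRC_CODE:
            raise ValueError(f"unknown hint source {self.source!r}")
        if self.multiplicity < 1:
            raise ValueError("hint multiplicity must be >= 1")

    @property
    def key(self) -> HintKey:
        loc = self.location
        return (loc.seq_id, self.kind, loc.start, loc.end, loc.strand)


class HintSet:
    """Keyed hint collection; one record per (key, source)."""

    def __init__(self, hints=()):
        self._records: dict[tuple[HintKey, str], Hint] = {}
        for h in hints:
            self.add(h)

    def add(self, hint: Hint) -> None:
        """Insert a hint; a same-key same-source record sums multiplicities."""
        rk = (hint.key, hint.source)
        existing = self._records.get(rk)
        if existing is None:
            self._records[rk] = hint
        else:
            self._records[rk] = replace(
                existing, multiplicity=existing.multiplicity + hint.multiplicity
            )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(
            sorted(self._records.values(), key=lambda h: (h.key, h.source))
        )

    def __contains__(self, key: HintKey) -> bool:
        return any(rk[0] == key for rk in self._records)

    def keys(self) -> set[HintKey]:
        return {rk[0] for rk in self._records}

    def get(self, key: HintKey, source: str) -> Hint | None:
        return self._records.get((key, source))

    def multiplicity(self, key: HintKey) -> int:
        """Total multiplicity across sources for ``key`` (0 if absent)."""
        return sum(
            h.multiplicity for rk, h in self._records.items() if rk[0] == key
        )

    def keys_of_kind(self, kind: str) -> set[HintKey]:
        return {rk[0] for rk in self._records if rk[0][1] == kind}


def introns_from_alignments(models, source: str = "rnaseq") -> HintSet:
    """Tally intron hints from spliced transcript/read models.

    Multiplicity of each hint is the number of models containing that exact
    intron key.
    """
    hints = HintSet()
    for t in models:
        for iv in introns_of(t):
            hints.add(Hint("intron", iv, source, 1))
    return hints


def filter_hints(h: HintSet, min_multiplicity: int) -> HintSet:
    """Keep hints with multiplicity >= min_multiplicity (inclusive)."""
    if min_multiplicity < 1:
        raise ValueError("min_multiplicity must be >= 1")
    return HintSet(x for x in h if x.multiplicity >= min_multiplicity)


def intersect_hints(rnaseq: HintSet, protein: HintSet) -> HintSet:
    """Intron hints whose key occurs in both sets; multiplicity = pairwise min.

    Hints of different kinds never intersect.  Output records are tagged with
    the rnaseq source.
    """
    protein_keys = {h.key: h.multiplicity for h in protein}
    out = HintSet()
    for h in rnaseq:
        if h.key in protein_keys:
            out.add(
                replace(h, multiplicity=min(h.multiplicity, protein_keys[h.key]))
            )
    return out


def merge_hints(a: HintSet, b: HintSet) -> HintSet:
    """Key union; the same key from two sources stays as two tagged records."""
    out = HintSet()
    for h in a:
        out._records[(h.key, h.source)] = h
    for h in b:
        rk = (h.key, h.source)
        if rk not in out._records:
            out._records[rk] = h
    return out


# ---------------------------------------------------------------------------
# AUGUSTUS-style hints GFF I/O: feature = intron|start|stop, attrs src=E|P;mult=N


def write_hints_gff(hints: HintSet, path) -> None:
    with open(path, "w") as fh:
        for h in hints:
            loc = h.location
            fh.write(
                f"{loc.seq_id}\thint\t{h.kind}\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tsrc={_SRC_CODE[h.source]};mult={h.multiplicity}\n"
            )


def read_hints_gff(path) -> HintSet:
    hints = HintSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            kind = f[2]
            if kind not in HINT_KINDS:
                raise ValueError(f"{path}:{lineno}: unknown hint kind {kind!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            src = _CODE_SRC.get(attrs.get("src", ""))
            if src is None:
                raise ValueError(f"{path}:{lineno}: missing/unknown src attribute")
            mult = int(attrs.get("mult", 1))
            loc = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            hints.add(Hint(kind, loc, src, mult))
    return hints
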