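"""Single-dose marker selection for a maternal haplotype linkage map.

In an autotetraploid F1 cross, markers usable for a single-parent haplotype
map are simplex in the mapped (maternal) parent and absent from the other:
dosage 0/0/0/1 x 0/0/0/0.  Such markers are expected to segregate 1:1
(present:absent) among progeny.  The filter keeps markers that

(a) are maternal simplex / paternal nulliplex,
(b) have strictly less than ``max_missing`` (default 5%) missing calls, and
(c) are not rejected by a chi-square goodness-of-fit test against 1:1 at
    significance ``alpha`` (default 0.05; no continuity correction, no
    multiplicity adjustment).

The audit table records, per marker, the first rule that failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

PRESENT, ABSENT, MISSING = "present", "absent", "missing"


@dataclass(frozen=True)
class DosageMarker:
    """One GBS variant: parental dosage genotypes + progeny presence calls."""

    marker_id: str
    seq_id: str
    position: int
    maternal_dosage: int
    paternal_dosage: int
    progeny_calls: tuple[str, ...]

    def __post_init__(self) -> None:
        for dose in (self.maternal_dosage, self.paternal_dosage):
            if not 0 <= dose <= 4:
                raise ValueError(f"{self.marker_id}: dosage {dose} outside 0-4")
        if not self.progeny_calls:
            raise ValueError(f"{self.marker_id}: no progeny calls")
        bad = set(self.progeny_calls) - {PRESENT, ABSENT, MISSING}
        if bad:
            raise ValueError(f"{self.marker_id}: unknown calls {bad}")

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_calls)

    @property
    def n_missing(self) -> int:
        return sum(c == MISSING for c in self.progeny_calls)

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_progeny

    @property
    def counts(self) -> tuple[int, int]:
        present = sum(c == PRESENT for c in self.progeny_calls)
        absent = sum(c == ABSENT for c in self.progeny_calls)
        return present, absent


def segregation_pvalue(present: int, absent: int) -> float:
    """Chi-square goodness-of-fit p-value against a 1:1 ratio."""
    n = present + absent
    if n == 0:
        return float("nan")
    chi2 = (present - absent) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def filter_single_dose(
    markers,
    max_missing: float = 0.05,
    alpha: float = 0.05,
) -> tuple[list[DosageMarker], pd.DataFrame]:
    """Apply the single-dose marker rules; return (kept, audit table).

    Rules, checked in order (a) dosage, (b) missingness (strict <), (c) 1:1
    segregation (keep iff p >= alpha); the audit table has one row per input
    marker with the outcome and the first failed rule.  A marker with zero
    non-missing progeny has missing fraction 1 and fails rule (b).
    """
    kept = []
    audit_rows = []
    for m in markers:
        present, absent = m.counts
        pval = segregation_pvalue(present, absent)
        if not (m.maternal_dosage == 1 and m.paternal_dosage == 0):
            outcome, failed = "rejected", "dosage"
        elif m.missing_fraction >= max_missing:
            outcome, failed = "rejected", "missing"
        elif not (pval >= alpha):
            outcome, failed = "rejected", "segregation"
        else:
            outcome, failed = "kept", ""
            kept.append(m)
        audit_rows.append(
            {
                "marker_id": m.marker_id,
                "maternal_dosage": m.maternal_dosage,
                "paternal_dosage": m.paternal_dosage,
                "missing_fraction": m.missing_fraction,
                "present": present,
                "absent": absent,
                "p_value": pval,
                "outcome": outcome,
                "failed_rule": failed,
            }
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "marker_id",
            "maternal_dosage",
            "paternal_dosage",
            "missing_fraction",
            "present",
            "absent",
            "p_value",
            "outcome",
            "failed_rule",
        ],
    )
    return kept, audit


# ---------------------------------------------------------------------------
# TSV I/O: columns marker_id, chrom, pos, maternal, paternal, then one column
# per progeny individual coded 1 (present) / 0 (absent) / NA (missing).

_CALL_CODE = {PRESENT: "1", ABSENT: "0", MISSING: "NA"}
_CODE_CALL = {"1": PRESENT, "0": ABSENT, "NA": MISSING}


def write_marker_tsv(markers, path) -> None:
    markers = list(markers)
    n = markers[0].n_progeny if markers else 0
    cols = ["marker_id", "chrom", "pos", "maternal", "paternal"] + [
        f"ind{i + 1}" for i in range(n)
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in markers:
            row = [
                m.marker_id,
                m.seq_id,
                str(m.position),
                str(m.maternal_dosage),
                str(m.paternal_dosage),
            ] + [_CALL_CODE[c] for c in m.progeny_calls]
            fh.write("\t".join(row) + "\n")


def read_marker_tsv(path) -> list[DosageMarker]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["marker_id", "chrom", "pos", "maternal", "paternal"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ind_cols = [c for c in df.columns if c not in required]
    markers = []
    for _, row in df.iterrows():
        calls = []
        for c in ind_cols:
            code = row[c]
            if code not in _CODE_CALL:
                raise ValueError(
                    f"{path}: marker {row['marker_id']}: bad call {code!r}"
                )
            calls.append(_CODE_CALL[code])
        markers.append(
            DosageMarker(
                marker_id=row["marker_id"],
                seq_id=row["chrom"],
                position=int(row["pos"]),
                maternal_dosage=int(row["maternal"]),
                paternal_dosage=int(row["paternal"]),
                progeny_calls=tuple(calls),
            )
        )
    return markers
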