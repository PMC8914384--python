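import math

import pytest

from ipenrich import ProteinRecord, ProteinTable


def quantile_oracle(values, level):
    """Brute-force linear-interpolation quantile, independent of numpy."""
    xs = sorted(values)
    pos = level * (len(xs) - 1)
    lo, hi = math.floor(pos), math.ceil(pos)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def fences_oracle(values, multiplier):
    """Brute-force boxplot fences from the quantile oracle."""
    q1 = quantile_oracle(values, 0.25)
    q3 = quantile_oracle(values, 0.75)
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def classify_oracle(ratio, others, m1=1.5, m2=3.0):
    """Class of ``ratio`` against fences computed from ``others``."""
    lo2, hi2 = fences_oracle(others, m2)
    lo1, hi1 = fences_oracle(others, m1)
    if ratio > hi2 or ratio < lo2:
        return 2
    if ratio > hi1 or ratio < lo1:
        return 1
    return 0


def make_record(pid, peptides=5, bait=1e7, control=1e6, **kwargs):
    return ProteinRecord(
        protein_ids=pid,
        peptides_razor_unique=peptides,
        lfq_bait=bait,
        lfq_control=control,
        **kwargs,
    )


@pytest.fixture
def twelve_record_table():
    """Hand-built table: 1 contaminant, 1 reverse decoy, 1 single-peptide,
    1 two-peptide protein with a missing control, and 8 clean records."""
    records = [
        make_record("CONTAM", is_contaminant=True),
        make_record("DECOY", is_reverse=True),
        make_record("ONEPEP", peptides=1),
        make_record("LOWEV_MISSING", peptides=2, control=None),
    ] + [make_record(f"CLEAN{i}", bait=10 ** (6 + 0.2 * i)) for i in range(8)]
    return ProteinTable(records=records)


PROTEIN_GROUPS_HEADER = (
    "Protein IDs\tGene names\tRazor + unique peptides\t"
    "LFQ intensity bait\tLFQ intensity control\t"
    "Potential contaminant\tReverse\tOnly identified by site"
)


def write_protein_groups_text(path, rows):
    """Write a proteinGroups-dialect file from raw tab-separated rows."""
    path.write_text("\n".join([PROTEIN_GROUPS_HEADER, *rows]) + "\n")
    return path
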