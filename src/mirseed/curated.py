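"""Curated values from the published sugarcane drought small-RNA survey.

These are transcribed published results used as inputs: the sorghum-homolog
mature reference set used for naming, per-library category counts, the TPM
values of the drought-responsive miRNAs in the two cultivars (HT = higher
drought tolerance, LT = lower tolerance; D/I = drought/irrigated, at 2 and 4
days of stress) together with the published signed fold changes, and the
printed miRNA/target alignment fragments with their expectation scores.

They feed the worked examples, the validation tests, and the reproduction
script; nothing here is computed by this package.
"""

from __future__ import annotations

#: Sorghum-homolog mature reference set (miRBase-style names, RNA alphabet).
#: One representative precursor name per distinct mature sequence.
REFERENCE_MATURES: dict[str, str] = {
    "sbi-MIR1432": "UCAGGAAAGAUGACACCAA",
    "sbi-MIR156b": "UUGACAGAAGAGAGUGAGCAC",
    "sbi-MIR160c": "UGCCUGGCUCCCUGUAUGCCA",
    "sbi-MIR164b": "UGGAGAAGCAGGGCACGUGCA",
    "sbi-MIR166a": "UCGGACCAGGCUUCAUUCCCC",
    "sbi-MIR167c": "UGAAGCUGCCAGCAUGAUCUGA",
    "sbi-MIR169f": "CUAGCCAAGAAUGACUUGCCU",
    "sbi-MIR169a": "CAGCCAAGGAUGACUUGCCGA",
    "sbi-MIR171h": "UUGAGCCGCGUCAAUAUCUCC",
    "sbi-MIR171g": "UGAUUGAGCCGUGCCAAUAUC",
    "sbi-MIR171c": "UGAGCCGAACCAAUAUCACUC",
    "sbi-MIR172a": "AGAAUCUUGAUGAUGCUGCAU",
    "sbi-MIR319b": "UUUGGAUUGAAGGGUGCU",
    "sbi-MIR390": "AAGCUCAGGAGGGAUAGCGCC",
    "sbi-MIR393b": "CUCCAAAGGGAUCGCAUUGAU",
    "sbi-MIR394a": "UUGGCAUUCUGUCCACCUCC",
    "sbi-MIR396d": "UCCACAGGCUUUCUUGAACUG",
    "sbi-MIR397": "UUGACUGCAGCGUUGAUGAGC",
    "sbi-MIR399a": "UGCCAAAGGAGAGUUGCCCUG",
    "sbi-MIR528": "UGGAAGGGGCAUGCAGAGGAG",
    "sbi-MIR529": "AGAAGAGAGAGAGUACAGCCU",
}

#: Published per-category read counts for two libraries (unique, total) and
#: the published percentages, used to validate percent recomputation.
#: Library HTD2: higher-tolerance cultivar, drought, day 2.
CATEGORY_COUNTS_HTD2: dict[str, dict[str, float]] = {
    "antisense exon": {"unique": 12762, "unique_pct": 0.50, "total": 108151, "total_pct": 1.22},
    "sense exon": {"unique": 76415, "unique_pct": 2.98, "total": 651383, "total_pct": 7.34},
    "miRNA": {"unique": 23950, "unique_pct": 0.94, "total": 1375593, "total_pct": 15.49},
    "rRNA": {"unique": 58355, "unique_pct": 2.28, "total": 925787, "total_pct": 10.43},
    "siRNA": {"unique": 59384, "unique_pct": 2.32, "total": 370579, "total_pct": 4.17},
    "snRNA": {"unique": 2094, "unique_pct": 0.08, "total": 7456, "total_pct": 0.08},
    "snoRNA": {"unique": 780, "unique_pct": 0.03, "total": 1516, "total_pct": 0.02},
    "tRNA": {"unique": 13254, "unique_pct": 0.52, "total": 549361, "total_pct": 6.19},
    "unannotated": {"unique": 2313810, "unique_pct": 90.35, "total": 4888685, "total_pct": 55.06},
}
CATEGORY_TOTALS_HTD2 = {"unique": 2560804, "total": 8878511}

CATEGORY_COUNTS_HTD4: dict[str, dict[str, float]] = {
    "antisense exon": {"unique": 15312, "unique_pct": 0.47, "total": 86674, "total_pct": 0.65},
    "sense exon": {"unique": 139293, "unique_pct": 4.24, "total": 814958, "total_pct": 6.10},
    "miRNA": {"unique": 26926, "unique_pct": 0.82, "total": 3467791, "total_pct": 25.95},
    "rRNA": {"unique": 63945, "unique_pct": 1.95, "total": 866844, "total_pct": 6.49},
    "siRNA": {"unique": 61333, "unique_pct": 1.87, "total": 552249, "total_pct": 4.13},
    "snRNA": {"unique": 4056, "unique_pct": 0.12, "total": 39774, "total_pct": 0.30},
    "snoRNA": {"unique": 1487, "unique_pct": 0.05, "total": 4854, "total_pct": 0.04},
    "tRNA": {"unique": 19375, "unique_pct": 0.59, "total": 1399409, "total_pct": 10.47},
    "unannotated": {"unique": 2951339, "unique_pct": 89.90, "total": 6128310, "total_pct": 45.87},
}
CATEGORY_TOTALS_HTD4 = {"unique": 3283066, "total": 13360863}

#: Drought-responsive miRNA TPM values and published signed fold changes.
#: Rows: (family, name, mature RNA, HTD, HTI, LTD, LTI, published HTD/HTI FC,
#: published LTD/LTI FC, HT asterisk, LT asterisk).
DE_TABLE_DAY2: list[tuple] = [
    ("miR164", "ssp-miR164", "UGGAGAAGCAGGGCACGUGCA", 95.07, 38.57, 45.43, 95.28, 2.46, -2.10, True, True),
    ("miR394", "ssp-miR394", "UUGGCAUUCUGUCCACCUCC", 5.19, 6.24, 2.30, 6.62, -1.20, -2.88, False, True),
    ("miR397", "ssp-miR397", "UUGACUGCAGCGUUGAUGAGC", 1873.63, 562.10, 799.76, 42.42, 3.33, 18.85, True, True),
    ("miR399", "ssp-miR399seq1", "UGCCAAAGGAGAGUUGCCC", 7.67, 5.18, 2.89, 6.30, 1.48, -2.18, False, True),
    ("miR528", "ssp-miR528", "UGGAAGGGGCAUGCAGAGGAG", 4674.10, 1445.14, 1874.15, 1025.19, 3.23, 1.83, True, False),
    ("miR1432", "ssp-miR1432", "UCAGGAAAGAUGACACCAA", 1687.91, 2300.44, 1053.92, 2583.96, -1.36, -2.45, False, True),
]

DE_TABLE_DAY4: list[tuple] = [
    ("miR393", "ssp-miR393", "CUCCAAAGGGAUCGCAUUGAU", 743.15, 808.97, 1220.51, 582.06, -1.09, 2.10, False, True),
    ("miR394", "ssp-miR394", "UUGGCAUUCUGUCCACCUCC", 2.33, 5.00, 4.64, 4.70, -2.14, -1.01, True, False),
    ("miR397", "ssp-miR397", "UUGACUGCAGCGUUGAUGAGC", 940.44, 1926.63, 858.82, 602.07, -2.05, 1.43, True, False),
    ("miR399", "ssp-miR399seq1", "UGCCAAAGGAGAGUUGCCC", 0.38, 1.61, 0.47, 2.56, -4.18, -5.51, True, True),
    ("miR528", "ssp-miR528", "UGGAAGGGGCAUGCAGAGGAG", 3717.14, 5397.83, 182.68, 3293.76, -1.45, -18.03, True, True),
]

#: Contrasts whose published FC disagrees with the value recomputed from the
#: published (rounded) TPM pair — the published FCs were evidently formed
#: from unrounded counts: miR399seq1 day-4 HT (-4.18 vs -4.24) and LT (-5.51
#: vs -5.45), miR394 day-4 HT (-2.14 vs -2.15).  Excluded from fold-change
#: recomputation checks.
FC_RECOMPUTATION_EXCLUDED = {
    ("ssp-miR399seq1", "day4", "HT"),
    ("ssp-miR399seq1", "day4", "LT"),
    ("ssp-miR394", "day4", "HT"),
}

#: Published miRNA/target alignments: miRNA fragment (5'->3'), target
#: fragment (5'->3'), published expectation, published inhibition call.
TARGET_ALIGNMENTS: dict[str, dict] = {
    "ssp-miR164/NAC": {
        "mirna_fragment": "UGGAGAAGCAGGGCACGUGC",
        "target_fragment": "GCAGGUGCCCUGCUUCUCCA",
        "expectation": 1.0,
        "inhibition": "cleavage",
        "target_accession": "SCEPRT2048G05.g",
    },
    "ssp-miR393/TIR1": {
        "mirna_fragment": "CUCCAAAGGGAUCGCAUUG",
        "target_fragment": "CAAUGCGAUCCCUUUGGAU",
        "expectation": 1.0,
        "inhibition": "cleavage",
        "target_accession": "TC120009",
    },
}

#: Number of distinct drought-responsive miRNAs reported across both days.
PUBLISHED_DISTINCT_DE_COUNT = 7


def distinct_de_mirnas(fc_min: float = 2.0) -> set[str]:
    """Distinct miRNA names with |signed FC| > fc_min in any published contrast.

    Recomputes the signed fold change from the published TPM pairs, so the
    set logic is independent of the printed asterisks.
    """
    from .diffexp import signed_fold_change

    names = set()
    for table in (DE_TABLE_DAY2, DE_TABLE_DAY4):
        for row in table:
            name, htd, hti, ltd, lti = row[1], row[3], row[4], row[5], row[6]
            for treated, control in ((htd, hti), (ltd, lti)):
                if abs(signed_fold_change(treated, control)) > fc_min:
                    names.add(name)
    return names
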