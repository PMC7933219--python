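"""Small published reference inputs used for validation.

These are printed results from the EC vs TC-EC (tumor-cell-adhered
endothelial cell) microarray study this package's statistics come from;
they serve as fixed inputs for validating the |Diffk| normalization and
the sequence arithmetic, not as values the package re-derives from raw
data.
"""

from __future__ import annotations

import pandas as pd

#: Published top-10 differentially connected mRNAs/lncRNAs between the EC
#: and TC-EC co-expression networks: per-condition degrees and the printed
#: |Diffk| (3 decimals).
REFERENCE_DIFFK_ROWS = [
    # feature_id, feature_type, k_ec, k_tcec, printed_diffk
    ("PRKAA2", "coding", 34, 7, 0.789),
    ("NLGN4X", "coding", 34, 9, 0.744),
    ("n339695", "non_coding", 34, 9, 0.744),
    ("ST6GALNAC3", "coding", 36, 12, 0.733),
    ("DGAT1", "coding", 36, 12, 0.733),
    ("TRIB1", "coding", 30, 5, 0.722),
    ("GRPR", "coding", 30, 5, 0.722),
    ("MLLT11", "coding", 34, 10, 0.722),
    ("n378130", "non_coding", 28, 3, 0.711),
    ("n410438", "non_coding", 31, 7, 0.706),
]

#: Maximum node degree of the EC co-expression network (printed as the
#: largest degree in the table).
EC_KMAX = 36

#: Maximum node degree of the TC-EC network.  Not printed directly; it is
#: the unique integer (with EC_KMAX = 36) under which the per-network
#: max-degree normalization reproduces every printed |Diffk| — recovered
#: by :func:`diffconn.diffk.infer_normalizers`.
TCEC_KMAX = 45


def reference_diffk_table() -> pd.DataFrame:
    """The published degree table as a DataFrame."""
    return pd.DataFrame(
        REFERENCE_DIFFK_ROWS,
        columns=["feature_id", "feature_type", "k_ec", "k_tcec", "printed_diffk"],
    )


#: Mature miR-124-3p sequence (RNA, 5'->3').
MIR_124_3P = "uaaggcacgcggugaaugcc"

#: Published antisense (DNA) of miR-124-3p used in the knockdown construct.
MIR_124_3P_ANTISENSE_DNA = "GGCATTCACCGCGTGCCTTA"

#: Published miR-124-3p binding-site positions on the PRKAA2 3'UTR
#: (1-based inclusive).  Checking them requires the user-supplied UTR
#: sequence; see the seed-scanner docs.
PRKAA2_UTR_SITE_POSITIONS = [(6166, 6172), (6893, 6899)]
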