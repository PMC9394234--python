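"""Bundled reference data: the 22-patient HHD-B-ALL discovery cohort.

Per diagnostic sample: clinical karyotype (as reported by conventional
cytogenetics or SNP array), demographics, outcome and follow-up, plus the
major subclone code and its blast percentage (PMC) determined by
sequential iFISH.  CR patients remained disease-free beyond 5 years of
follow-up; REL patients relapsed within that window (REL07 at 7 years).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_discovery_cohort"]

# case, outcome, sex, age, wbc(1e9/L), follow-up years, relapse, death,
# protocol, karyotype (first abnormal clone rule applies), seq-iFISH major
# clone code (gains for X,4,6,10,14,17,18,21), PMC (%), karyotype_concordant
_DISCOVERY = [
    ("CR01", "CR", "M", 3, 195.0, 14.0, False, False, "COALL03-HR-S",
     "58,XY,+X,-Y,+4,+6,+8,+10,+11,+12,+14,+17,+18,+21,+21,+22 (SNP6)",
     "01110111", 4.74, False),
    ("CR02", "CR", "F", 2, 9.0, 9.6, False, False, "COALL03LR-R",
     "53,XX,+X,+X,+6,+14,+17,+21,+21 (SNP6)", "10001102", 7.95, False),
    ("CR03", "CR", "M", 8, None, 5.5, False, False, "SEHOP/PETHEM2013",
     "55 XXYY,+4,+6,+12,+15,+18,+21", "11111111", 7.12, False),
    ("CR04", "CR", "F", 4, 8.2, 8.2, False, False, "ALL10-MR",
     "54,XX,+X,+6,+8,+14,+17,+18,+21,+21[15]/54,idem,-13,+mar[11]/46,XX[19]",
     "10101102", 7.39, False),
    ("CR05", "CR", "F", 2, 4.0, 13.3, False, False, "COALL03-LR-R",
     "57,XX,+X,+X,+4,+6,+8,+10,+14,+17,+18,+21,+21 (SNP6)",
     "21111111", 10.85, False),
    ("CR06", "CR", "M", 3, 33.9, 16.0, False, False, "PETHEMA LAL96",
     "54,X,+X,Y,+6,+10,+14,+17,+18,+21,+mar[30]", "10111111", 12.95, True),
    ("CR07", "CR", "M", 2.3, 25.4, 9.0, False, False, "SHOP-2005",
     "55,XXY,+3,+4,+6,+10,+14,+18,+21,+21/46,XY", "11111012", 8.0, True),
    ("CR08", "CR", "M", 6, 2.67, 11.0, False, False, "SHOP-2005",
     "60,XY,+X,+4,+6,+7,+8,+9,+14,+17,+18,+21,+21,+3mar/46,XY",
     "11112122", 3.96, False),
    ("CR09", "CR", "M", 13, 4.2, 7.0, False, False, "SHOP-2005",
     "57,XXY,+4,+6,+8,+10,+10?,+13,+14,+17,+18,+21[14]/46,XY[16]",
     "11121111", 2.55, True),
    ("CR10", "CR", "F", 3, 9.7, 7.0, False, False, "SHOP-2005",
     "54,XXX,+4,+6,+8,inv(9)(p11q12),+14,+17,+18,+21[22]"
     "/46,XX,inv(9)(p11q12)[2]", "11101111", 7.72, True),
    ("REL01", "REL", "M", 6, 4.2, 4.4, True, True, "UKALL2003-SR",
     "59,XY,+?X,+4,+6,+7,+8,+12,+14,+?add(17)(p1),+18,+18,+21,"
     "+der(?)t(?;5)(?;q?13),+mar[6]/63,idem,dup(1)(q2q3),+22,inc[7]/46,XY[5]",
     "11121121", 3.61, False),
    ("REL02", "REL", "F", 2, 119.0, 3.6, True, False, "UKALL2003-B",
     "51,XX,+X,+8,+14,+21,+21[5]/46,XX[9]", "10001002", 30.32, True),
    ("REL03", "REL", "M", 13, 1.2, 4.2, True, False, "UKALL2003-B",
     "54,XY,+X,+4,+6,+10,+14,+add(19)(p13),+20,+21[cp8]",
     "11111102", 10.36, False),
    ("REL04", "REL", "F", 13, 4.1, 2.6, True, True, "UKALL2003-A",
     "46,XX[20]/High hyperdiploid by FISH", "01112002", 22.3, False),
    ("REL05", "REL", "M", 8, 47.0, 3.5, True, True, "UKALL2003-A",
     "52-56,XY,+X,dup(1)(q25q44),+4,+8,+10,+11,+14,+18,+21,+21,+mar[cp7]"
     "/46,XY[3]", "11011002", 9.09, False),
    ("REL06", "REL", "M", 8, 7.8, 4.2, True, True, "UKALL2003-A",
     "46,XY[20]/High hyperdiploid by FISH", "11111111", 5.83, False),
    ("REL07", "REL", "M", 2, 55.0, 7.2, True, False, "UKALL2003-C",
     "56,XY,+X,ins(1;?),(q21.3;?),+4,+6,+14,+17,+18,+21,+21,+22,+mar[5]"
     "/46,XY[5]", "11101112", 12.0, True),
    ("REL08", "REL", "M", 8, 44.6, 4.6, True, False, "UKALL2003-A",
     "High hyperdiploid by FISH", "10001002", 11.57, False),
    ("REL09", "REL", "F", 3, 31.7, 3.3, True, True, "UKALL2003-A",
     "51,XX,+X,+6,+14,+21,+21[16]/51,idem,add(9)(q34)[2]/46,XX[2]",
     "10101002", 10.85, True),
    ("REL10", "REL", "F", 2, 43.9, 2.0, True, True, "PETHEMA LAL 96",
     "53,XX,+4,+6,+14,+17,+18,+2mar[8]/46,XX[22]", "11101111", 7.86, False),
    ("REL11", "REL", "M", 5, 0.54, 2.0, True, True, "LAL-SHOP-2005",
     "59,XXY,+Y,der(1)(q?),+4,+5,+6,+8,+10,+11,+18,+18,+21,+22,mar[9]"
     "/46,XY[41]", "12120022", 8.45, False),
    ("REL12", "REL", "M", 5, None, 0.5, True, False, "PETHEMA LAL 96",
     "57,XY,der(1)(p?q?),+4,10mar[56%]/46,XY[44%]", "11121012", 10.61, False),
]

_COLUMNS = [
    "case", "outcome", "sex", "age", "wbc", "time_years", "relapse", "death",
    "protocol", "karyotype", "major_clone", "pmc", "karyotype_concordant",
]


def load_discovery_cohort() -> pd.DataFrame:
    """Return the 22 diagnostic discovery-cohort samples as a DataFrame.

    ``karyotype_concordant`` flags the cases whose cytogenetic major clone
    was reported to coincide with the seq-iFISH major subclone; it is the
    ground truth against which :func:`clonefish.karyotype.karyotype_concordance`
    is checked.
    """
    return pd.DataFrame(_DISCOVERY, columns=_COLUMNS)
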