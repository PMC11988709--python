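import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sgidpep import Peptide  # noqa: E402

#: (hydrophobic %, basic %, acidic %, neutral %, MW, length) as tabulated for
#: the 13 characterised resistant peptides. Rows whose printed percentages
#: contradict the four-class footnote definition are flagged footnote_ok=False.
TABLE3 = {
    "QCCDFMK": dict(mw=874.07, length=7, footnote_ok=False),
    "HGGGGGGFGGGGFSR": dict(mw=1263.28, length=15, footnote_ok=False),
    "KCCDMMK": dict(mw=858.14, length=7, footnote_ok=False),
    "PSPSLVWR": dict(mw=941.08, length=8, footnote_ok=True, hydrophobic=62.50,
                     basic=12.50, acidic=0.00, neutral=25.00),
    "EWGGGGCGGGGGVSSLR": dict(mw=1492.58, length=17, footnote_ok=False),
    "SGGFGGNFGNR": dict(mw=1069.09, length=11, footnote_ok=False),
    "RHWLPR": dict(mw=864.01, length=6, footnote_ok=False),
    "SDWPELLGR": dict(mw=1072.17, length=9, footnote_ok=False),
    "SGGGGGGLGSGGSLR": dict(mw=1175.21, length=15, footnote_ok=False),
    "YNLPMLR": dict(mw=906.11, length=7, footnote_ok=False),
    "HGGGGGGFGGGGFDK": dict(mw=1263.28, length=15, footnote_ok=False),
    "SDTLFFAR": dict(mw=956.05, length=8, footnote_ok=True, hydrophobic=50.00,
                     basic=12.50, acidic=12.50, neutral=25.00),
    "LLFPMSR": dict(mw=863.08, length=7, footnote_ok=True, hydrophobic=71.43,
                    basic=14.29, acidic=0.00, neutral=14.29),
}


@pytest.fixture(scope="session")
def table3_peptides():
    return {seq: Peptide(seq) for seq in TABLE3}
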