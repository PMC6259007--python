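"""Summary-statistic tests on published demographic tables.

Welch t, Yates-corrected chi-square and variance-ratio F recomputed from
printed group means/SDs/counts — no case-level data required.
"""
import symnet as sn
from symnet.group_stats import GroupSummary

fx = sn.table1_fixture()
g = lambda r: GroupSummary(r.mean, r.sd, r.n)  # noqa: E731

t = sn.welch_t(g(fx.ces["subthreshold"]), g(fx.ces["full"]))
print(f"CES, full vs subthreshold: t({t.df:.1f}) = {t.statistic:.2f}, p = {t.p:.2g}")

chi = sn.chi2_2x2(
    fx.gender["subthreshold"]["female"], fx.gender["subthreshold"]["male"],
    fx.gender["full"]["female"], fx.gender["full"]["male"],
)
print(f"gender by severity group: chi2(1) = {chi.statistic:.3f}, p = {chi.p:.3f}")

f = sn.variance_ratio_f(
    fx.dts["full"].sd, fx.dts["full"].n,
    fx.dts["subthreshold"].sd, fx.dts["subthreshold"].n,
)
print(f"DTS variance ratio: F = {f.statistic:.2f}, p = {f.p:.3f}")
print("(a significant F means symptom-severity spread differs between groups)")

# scoring rules
print("\nCES 24 ->", sn.combat_group(24), "; CES 25 ->", sn.combat_group(25))
print("criteria A,E,F + B,C ->", sn.subthreshold_status(True, True, True, False, True, True))
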