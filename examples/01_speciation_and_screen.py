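"""Speciation of the study compounds and the solubility design screen.

Builds nothing: loads the bundled 19-compound property table, evaluates
the Henderson–Hasselbalch neutral fraction at the three batch pH levels,
and checks each initial concentration against 1% of water solubility.
"""

from phsorb import read_compound_table, solubility_screen, speciate
from phsorb.synthetic import default_c0

records = read_compound_table()
print(f"{'compound':<16} {'class':<8} f_n(pH4)  f_n(pH7)  f_n(pH10)  c0/WS")
for rec in records:
    fns = [speciate(rec, ph).f_n for ph in (4.0, 7.0, 10.0)]
    ratio = solubility_screen(rec, default_c0(rec.name))
    ratio_txt = "liquid" if ratio is None else f"{100 * ratio:.3f}%"
    print(
        f"{rec.name:<16} {rec.ion_class:<8} "
        f"{fns[0]:.3e} {fns[1]:.3e} {fns[2]:.3e}  {ratio_txt}"
    )

print(
    "\nf_n is the neutral fraction: acids lose it as pH rises, bases gain"
    "\nit, neutral compounds stay at 1. The last column is the initial"
    "\nconcentration as a share of water solubility; every value below 1%"
    "\nmeans the batch design avoids competitive sorption."
)
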