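"""Model apparent avian species richness as a Poisson GLM.

Reads the per-wetland-year richness table written by 01_simulate_study.py
and fits log E[richness] ~ wetland type + standardized size + year,
writing the coefficient table and a text report to results/richness/.
"""

from pathlib import Path

import wetlandbirds as wb
from wetlandbirds.richness_glm import format_glm_report

DATA = Path("results/data")
OUT = Path("results/richness")


def main() -> None:
    rt = wb.read_richness_table(DATA / "s4_richness.csv")
    glm = wb.fit_poisson_glm(rt)
    OUT.mkdir(parents=True, exist_ok=True)
    glm.summary().to_csv(OUT / "richness_glm.csv")
    report = format_glm_report(glm)
    (OUT / "richness_glm.txt").write_text(report + "\n")
    print(report)
    print()
    size_p = glm.p_values["size"]
    direction = "positively" if glm.coefficients["size"] > 0 else "negatively"
    verdict = "associated" if size_p < 0.05 else "not clearly associated"
    print(f"richness is {direction} {verdict} with wetland size "
          f"(log proportional change per SD = "
          f"{glm.coefficients['size']:.2f}, p = {size_p:.3g})")


if __name__ == "__main__":
    main()
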