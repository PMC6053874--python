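"""Hammett analysis of the first deprotonation site.

Classifies every 4-substituent as electron-donating (sigma_p < 0) or
electron-withdrawing (sigma_p > 0), assigns the first deprotonating
hydroxyl (OH_m or OH_p) from the computed site pKa values, and flags the
compounds that break the sigma-sign trend (the weakly deactivating
chloro and hydroxyl substituents).  Writes the assignment table to
results/.
"""

from pathlib import Path

import pandas as pd

from dhbpka import first_deprotonation_site, paper_fixtures

RESULTS = Path("results")


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for rec in paper_fixtures():
        s = first_deprotonation_site(rec)
        rows.append(
            {
                "compound": rec.name,
                "substituent": rec.substituent,
                "sigma_p": rec.sigma_p,
                "class": s.substituent_class.value,
                "first_hydroxyl_site": s.first_hydroxyl_site,
                "substituent_proton_most_acidic": s.rh_is_global_minimum,
                "exception_to_trend": s.exception,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "deprotonation_sites.csv", index=False)
    print(table.to_string(index=False))
    exceptions = table.loc[table["exception_to_trend"], "compound"].tolist()
    print(f"\ntrend exceptions: {exceptions}")


if __name__ == "__main__":
    main()
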