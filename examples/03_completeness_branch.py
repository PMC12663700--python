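"""Completeness branch: how differently did the sites *skip* questions?

Classifies every cell as ordinary-missing / not-applicable / observed,
reduces the three-code matrix by multiple correspondence analysis, and runs
the same histogram -> Jensen-Shannon simplex chain on the missingness
profiles, per section.
"""

import warnings

from msvdq import make_paper_replica, run_completeness_analysis

ds, codebook = make_paper_replica()
for section in ("all", "interpersonal communication", "health data"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_completeness_analysis(ds, codebook, section=section)
    worst = max(res.msv.spo, key=res.msv.spo.get)
    print(f"{section:30s} GPD={res.msv.gpd:.3f}  "
          f"most outlying site: {worst} (SPO={res.msv.spo[worst]:.3f})")
# Site C tops the SPO ranking wherever its concentrated missingness was
# injected; sections where every site skips at the same base rate score a
# much lower GPD.
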