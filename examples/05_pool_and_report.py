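"""Full pipeline on a desk-scale cohort: simulate -> impute -> fit -> pool.

Runs two skills x two imputations with short chains, pools the fits with
Rubin's rules and prints the report: per-skill mean course effect (logit),
its odds multiplier, and the ~95% range of individual course effects.
"""

import tempfile
from pathlib import Path

from ordmm import cohort as sc
from ordmm import impute as imp
from ordmm import model as mdl
from ordmm.pipeline import RunConfig, report, run

out = Path(tempfile.mkdtemp()) / "run"
config = RunConfig(
    out_dir=str(out), seed=7, preset="desk", skills=(1, 2),
    design=sc.CohortDesign.small(80, 8),
    plan=sc.MissingnessPlan(blocks=(("A", 0),), item_rate=0.05),
    imputation=imp.ImputationConfig(m=2, n_cycles=2),
    mcmc=mdl.McmcConfig(n_chains=2, n_iter=900, n_warmup=400),
)
run(config)
print(report(out))
print("\nbeta is the pooled mean course effect in logit units; odds=exp(beta)"
      "\nis the multiplicative change in the odds of higher proficiency per"
      "\ncourse; the range is beta +/- 1.96 * sigma_c, covering ~95% of"
      "\nindividual course effects under the normal assumption.")
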