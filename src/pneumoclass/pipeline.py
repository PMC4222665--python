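"""End-to-end convenience: bundle in, labelled cohort out."""

from __future__ import annotations

import pandas as pd

from .bundle import CohortBundle, validate_bundle
from .classify import classify_episodes
from .codes import AnalysisConfig, default_config
from .covariates import attach_covariates_and_outcomes
from .episodes import deduplicate, find_candidates

__all__ = ["run_pipeline"]


def run_pipeline(
    bundle: CohortBundle,
    config: AnalysisConfig | None = None,
    check: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidates -> incident episodes -> subtype labels -> covariates/outcomes.

    Returns ``(cohort, suppressed)``: one row per incident episode with
    subtype, qualifying reason, exposure profile, covariate flags, aetiology
    and outcomes attached, plus the audit frame of suppressed repeat
    admissions.  With ``check=True`` the bundle is validated first and a
    dirty bundle raises ``ValueError`` listing the violations.
    """
    config = config or default_config()
    if check:
        violations = validate_bundle(bundle)
        if violations:
            raise ValueError(
                "bundle failed validation:\n" + "\n".join(violations[:50])
            )
    candidates = find_candidates(bundle, config)
    episodes, suppressed = deduplicate(candidates, config.dedup_window_days)
    if episodes.empty:
        return episodes.assign(subtype=pd.Series(dtype=object)), suppressed
    labeled = classify_episodes(episodes, bundle, config)
    cohort = attach_covariates_and_outcomes(labeled, bundle, config)
    return cohort, suppressed
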