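"""Public surface for expected-SFS prediction and spectrum transforms.

Prediction is analytic (exact) for single-population histories and
Monte-Carlo for structured models with migration and pulses; both return
per-site SNP-density spectra that scale to absolute counts via
:func:`scale_to_counts`.
"""

from .analytic import (  # noqa: F401
    expected_branch_times,
    expected_sfs_analytic,
    subtend_probability_matrix,
)
from .montecarlo import (  # noqa: F401
    BranchLengthStats,
    expected_sfs_montecarlo,
)
from .sfs import (  # noqa: F401
    ScalingParams,
    SFSSpectrum,
    drop_singletons_renormalize,
    fold,
    marginalize_joint,
    project,
    read_sfs,
    scale_to_counts,
    write_sfs,
)

__all__ = [
    "SFSSpectrum",
    "ScalingParams",
    "BranchLengthStats",
    "expected_branch_times",
    "expected_sfs_analytic",
    "expected_sfs_montecarlo",
    "subtend_probability_matrix",
    "fold",
    "project",
    "marginalize_joint",
    "scale_to_counts",
    "drop_singletons_renormalize",
    "read_sfs",
    "write_sfs",
]
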