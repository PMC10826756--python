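"""Small shared helpers."""

import numpy as np


def json_default(o):
    """Coerce numpy scalars for json.dumps(default=...)."""
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)!r}")
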