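"""Shared physical constants and unit conventions.

All internal quantities are SI.  Accelerations reported in multiples of
gravity are converted at the I/O boundary using ``G_STANDARD``.
"""

#: Standard gravity used to convert g-multiples to m/s^2.
G_STANDARD: float = 9.81
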