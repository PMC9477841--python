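"""Exception types.

``InputError`` covers everything caused by user-supplied data or
configuration (bad files, missing columns, invalid coordinates); the CLI
maps it to exit status 2. Anything else escaping the library is treated
as an internal error (exit status 1).
"""


class InputError(ValueError):
    """Invalid user input: malformed file, missing column, bad coordinate."""
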