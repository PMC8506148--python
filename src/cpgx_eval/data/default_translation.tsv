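gene	function_a	function_b	label
CYP2C19	normal	normal	normal
CYP2C19	normal	no	intermediate
CYP2C19	no	no	poor
CYP2C19	increased	normal	rapid
CYP2C19	increased	increased	ultrarapid
CYP2C19	increased	no	intermediate
CYP2B6	normal	normal	normal
CYP2B6	normal	decreased	intermediate
CYP2B6	normal	no	intermediate
CYP2B6	decreased	decreased	poor
CYP2B6	decreased	no	poor
CYP2B6	no	no	poor
CYP2B6	increased	normal	rapid
CYP2B6	increased	increased	ultrarapid
CYP2B6	increased	decreased	normal
CYP2B6	increased	no	intermediate
CYP3A5	normal	normal	extensive
CYP3A5	normal	no	intermediate
CYP3A5	no	no	poor
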