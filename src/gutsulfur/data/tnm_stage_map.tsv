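# Simplified colorectal TNM -> stage lookup (AJCC/ACS convention).
# '*' matches any normalized token. Rows are evaluated top to bottom; the first
# match wins. Tokens are normalized before lookup (prefixes p/c/y stripped,
# subletter suffixes a/b/c stripped, case-insensitive). Unmatched -> unstaged.
t	n	m	stage
*	*	M1	IV
*	N1	M0	III
*	N2	M0	III
T1	N0	M0	I
T2	N0	M0	I
T3	N0	M0	II
T4	N0	M0	II
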