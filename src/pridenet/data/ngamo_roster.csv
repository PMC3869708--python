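id,sex,birth_date,age_class,present_from,present_to
MI,male,2003-01-15,adult,2010-09-15,
AS,female,2004-06-15,adult,2010-09-01,
KE,female,2004-06-15,adult,2010-09-01,
KW,female,2004-09-15,adult,2010-09-01,
NL,female,2005-01-15,adult,2010-09-01,
NR,female,2005-01-15,adult,2010-09-01,
PH,female,2004-03-15,adult,2010-09-01,
AT1,female,2011-01-06,cub,2011-01-06,
AS4,female,2011-10-20,cub,2011-10-20,
AS5,female,2011-10-20,cub,2011-10-20,
KE3,female,2011-11-05,cub,2011-11-05,
KE4,female,2011-11-05,cub,2011-11-05,
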