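>BdCESA1
--------RMMKRTESSAPIFNMEDIEEGIE--GYEDERSMLMSQKRLEKRFGQSPIFTA
>BdCESA3
--------KSNKHVDSSVPVFNLEDIEEGVEGAGFDDEKSLLMSQMSLEKRFGQSAAFVA
>BdCESA6
--------LFFKRAENQSPAYALGEIEEGIPGA--ENDKAGIVNQEKLEKKFGQSSVFAA
>BdCESA9
----------LRRTMSVVPLLESEEDEEGIAEGGR--RRRLRSYSAALERHFGQSPLFIA
>BdCESA4
KDKLGGAPKKGGSYRKQQRGFELEEIEEGIEGYD-ELERSSLMSQKNFEKRFGQSPVFIA
>BdCESA7
-----GLP---------------ESVGDGMDG-----DKEMLMSQMNFEKRFGQSAAFVT
>BdCESA8
--------RDSRREDLESAIFNLREIDNY-----DEYERSMLISQMSFEKSFGQSSVFIE
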