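env_id	n_pairs
2002HRB	NA
2003HRB	NA
2004HRB	87027
2005HRB	1098849
2006HRB	5612873
2007HRB	3391676
2007HXL	24689
2007JMS	4059216
2008HRB	2133998
2008HXL	2731592
2008JMS	60238
2009HRB	NA
2009HXL	7432164
2009JMS	NA
2010HRB	NA
2010HXL	NA
2010JMS	NA
2011HRB	NA
2011HXL	NA
2011JMS	4113031
2012HRB	NA
2012HXL	5697403
2012JMS	NA
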