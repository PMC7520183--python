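location,location_name,environment,abundance,year,month,n_female,n_male
BC,Belle Chain,Rocky reef,834,2012,June,2,5
BC,Belle Chain,Rocky reef,834,2012,July,1,9
BC,Belle Chain,Rocky reef,834,2012,Aug,18,17
BC,Belle Chain,Rocky reef,834,2012,Sept,19,12
BC,Belle Chain,Rocky reef,834,2013,Aug,5,5
BC,Belle Chain,Rocky reef,834,2013,Sept,14,13
BC,Belle Chain,Rocky reef,834,2013,Oct,3,12
BI,Baby Island,Near estuary,<100,2016,Apr,7,7
BI,Baby Island,Near estuary,<100,2016,May,27,36
BI,Baby Island,Near estuary,<100,2016,June,8,12
BI,Baby Island,Near estuary,<100,2016,July,8,3
CB,Cowichan Bay,Estuary,167,2012,June,9,7
CB,Cowichan Bay,Estuary,167,2012,July,16,20
CB,Cowichan Bay,Estuary,167,2012,Aug,7,13
CB,Cowichan Bay,Estuary,167,2012,Sept,19,7
CB,Cowichan Bay,Estuary,167,2012,Oct,13,16
CB,Cowichan Bay,Estuary,167,2012,Nov,2,4
CB,Cowichan Bay,Estuary,167,2013,Apr,10,1
CB,Cowichan Bay,Estuary,167,2013,May,11,4
CB,Cowichan Bay,Estuary,167,2013,June,9,3
CB,Cowichan Bay,Estuary,167,2013,July,8,7
CB,Cowichan Bay,Estuary,167,2013,Aug,15,4
CB,Cowichan Bay,Estuary,167,2013,Sept,12,10
CB,Cowichan Bay,Estuary,167,2013,Oct,12,9
CB,Cowichan Bay,Estuary,167,2013,Nov,7,8
CB,Cowichan Bay,Estuary,167,2014,May,6,10
CB,Cowichan Bay,Estuary,167,2014,June,6,8
CB,Cowichan Bay,Estuary,167,2014,July,0,1
CB,Cowichan Bay,Estuary,167,2014,Aug,2,3
CB,Cowichan Bay,Estuary,167,2014,Sept,8,9
CB,Cowichan Bay,Estuary,167,2014,Oct,24,37
CB,Cowichan Bay,Estuary,167,2014,Nov,1,23
CM,Comox,Near Estuary,121,2012,May,4,15
CM,Comox,Near Estuary,121,2012,June,11,18
CM,Comox,Near Estuary,121,2012,July,13,22
CM,Comox,Near Estuary,121,2012,Aug,9,11
CM,Comox,Near Estuary,121,2012,Sept,20,10
CM,Comox,Near Estuary,121,2012,Oct,16,8
CM,Comox,Near Estuary,121,2013,Apr,4,13
CM,Comox,Near Estuary,121,2013,May,12,5
CM,Comox,Near Estuary,121,2013,June,5,8
CM,Comox,Near Estuary,121,2013,July,7,11
CM,Comox,Near Estuary,121,2013,Aug,10,10
CM,Comox,Near Estuary,121,2013,Sept,16,9
CM,Comox,Near Estuary,121,2013,Oct,11,7
FR,Fraser River,Estuary,76,2012,May,0,13
FR,Fraser River,Estuary,76,2012,June,3,17
FR,Fraser River,Estuary,76,2012,July,2,21
FR,Fraser River,Estuary,76,2012,Aug,2,6
FR,Fraser River,Estuary,76,2012,Sept,13,29
FR,Fraser River,Estuary,76,2012,Oct,5,13
FR,Fraser River,Estuary,76,2013,Apr,5,9
FR,Fraser River,Estuary,76,2013,May,4,15
FR,Fraser River,Estuary,76,2013,June,1,3
FR,Fraser River,Estuary,76,2013,July,1,5
FR,Fraser River,Estuary,76,2013,Aug,3,2
FR,Fraser River,Estuary,76,2013,Sept,7,20
FR,Fraser River,Estuary,76,2013,Oct,5,12
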